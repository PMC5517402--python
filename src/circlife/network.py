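"""Assemble per-stage circRNA–miRNA–mRNA sponge triplets.

A triplet is one miRNA that targets both a circRNA and an mRNA, where every
hit has already passed its score cutoff and the expression anti-correlation
filter, and all three molecules clear their stage fold-change gates:
2-fold for the miRNA (|log2 FC| >= 1) and 4-fold for the circRNA and the
mRNA (|log2 FC| >= 2) at any day within the stage. Triplets are unique
(circRNA, miRNA, mRNA) triples per stage.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .sponge_targets import CorrelationFilterResult

#: Fold-change gates on |log2 FC|: miRNAs 2-fold, circRNAs and mRNAs 4-fold.
DEFAULT_GATES = {"mirna": 1.0, "circ": 2.0, "mrna": 2.0}


@dataclass(frozen=True, order=True)
class Triplet:
    circ_id: str
    mirna_id: str
    mrna_id: str
    stage: str
    circ_score: float
    mrna_score: float
    rho_circ: float
    rho_mrna: float


def gate_features(fc_profiles: pd.DataFrame, threshold: float) -> set[str]:
    """Feature ids whose |log2 FC| reaches the threshold at any stage day."""
    if fc_profiles.empty:
        return set()
    hit = fc_profiles.abs().max(axis=1) >= threshold
    return {str(f) for f in fc_profiles.index[hit]}


def assemble_triplets(
    circ_hits: list[CorrelationFilterResult],
    mrna_hits: list[CorrelationFilterResult],
    gated_circ: set[str],
    gated_mrna: set[str],
    gated_mirna: set[str],
    stage: str,
) -> list[Triplet]:
    """One triplet per (circRNA, miRNA, mRNA) with a shared gated miRNA.

    ``circ_hits``/``mrna_hits`` are anti-correlation filter results; only
    passed hits on gated molecules participate. Output is deduplicated and
    sorted (circRNA, miRNA, mRNA) for determinism.
    """
    circ_by_mirna: dict[str, list[CorrelationFilterResult]] = {}
    for res in circ_hits:
        if res.passed and res.hit.mirna_id in gated_mirna and res.hit.target_id in gated_circ:
            circ_by_mirna.setdefault(res.hit.mirna_id, []).append(res)

    mrna_by_mirna: dict[str, list[CorrelationFilterResult]] = {}
    for res in mrna_hits:
        if res.passed and res.hit.mirna_id in gated_mirna and res.hit.target_id in gated_mrna:
            mrna_by_mirna.setdefault(res.hit.mirna_id, []).append(res)

    triplets: set[Triplet] = set()
    for mirna_id, circs in circ_by_mirna.items():
        for c in circs:
            for m in mrna_by_mirna.get(mirna_id, ()):
                triplets.add(
                    Triplet(
                        circ_id=c.hit.target_id,
                        mirna_id=mirna_id,
                        mrna_id=m.hit.target_id,
                        stage=stage,
                        circ_score=c.hit.score,
                        mrna_score=m.hit.score,
                        rho_circ=c.rho,
                        rho_mrna=m.rho,
                    )
                )
    return sorted(triplets)


def network_stats(triplets_by_stage: dict[str, list[Triplet]]) -> dict:
    """Triplet and node counts per stage plus the miRNA degree distribution.

    A miRNA's degree counts its distinct circRNA and mRNA partners.
    """
    out: dict = {}
    for stage, triplets in triplets_by_stage.items():
        circs = {t.circ_id for t in triplets}
        mirnas = {t.mirna_id for t in triplets}
        mrnas = {t.mrna_id for t in triplets}
        degree: Counter[str] = Counter()
        for mi in mirnas:
            partners = {t.circ_id for t in triplets if t.mirna_id == mi} | {
                t.mrna_id for t in triplets if t.mirna_id == mi
            }
            degree[mi] = len(partners)
        out[stage] = {
            "n_triplets": len(triplets),
            "n_circ": len(circs),
            "n_mirna": len(mirnas),
            "n_mrna": len(mrnas),
            "mirna_degree": dict(sorted(degree.items())),
        }
    return out
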