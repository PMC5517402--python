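"""Plant-style miRNA target scoring on mRNAs and circular RNAs.

The scorer is a gapless penalty scheme of the psRNATarget family: the miRNA
(5'→3') is aligned against a target window of its own length read 3'→5';
each Watson–Crick pair costs 0, each G:U wobble 0.5 and each mismatch 1, with
penalties doubled inside the seed region (miRNA positions 2–13 from the 5'
end). A score of 0 therefore means perfect complementarity over the full
miRNA. Hits are retained when the score is at or below a per-molecule-type
cutoff — by convention 4.0 for mRNAs and a slightly looser 4.5 for circRNAs.

Because circRNAs are covalently closed, target sites may span the back-splice
seam; scanning a circular target additionally slides over the
junction-spanning window produced by sequence extraction.

Retained hits are finally filtered by expression anti-correlation: the miRNA
and its putative target must show Spearman rho <= -0.5 (inclusive) across the
full 14-point time course, the signature expected of an active
sponge/cleavage relationship.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

#: Default retention cutoffs per target kind.
DEFAULT_CUTOFFS = {"mRNA": 4.0, "circRNA": 4.5}

#: Seed region, 1-based positions from the miRNA 5' end (inclusive).
DEFAULT_SEED_REGION = (2, 13)

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


class SequenceError(ValueError):
    """A sequence contains non-nucleotide characters or has the wrong length."""


@dataclass(frozen=True)
class TargetHit:
    mirna_id: str
    target_id: str
    kind: str                    # "mRNA" or "circRNA"
    start: int                   # 1-based window start on the target sequence
    junction_spanning: bool
    score: float
    alignment: str               # miRNA 5'->3': '|' pair, 'o' wobble, '.' mismatch


@dataclass(frozen=True)
class CorrelationFilterResult:
    hit: TargetHit
    rho: float                   # NaN when undefined (constant profile)
    passed: bool


def _encode(seq: str, what: str) -> np.ndarray:
    try:
        return np.array([_ENC[b] for b in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise SequenceError(f"{what}: non-nucleotide character {exc.args[0]!r}") from None


def _penalty_matrix(
    mirna: np.ndarray,
    windows: np.ndarray,
    seed_region: tuple[int, int],
    wobble_penalty: float,
    mismatch_penalty: float,
    seed_multiplier: float,
) -> np.ndarray:
    """Per-position penalties for each window (rows) against the miRNA.

    ``windows[w, i]`` must hold the target base pairing miRNA position ``i``,
    i.e. windows already reversed so the target is read 3'→5'. Encoded bases
    sum to 3 for a Watson–Crick pair and 5 for the G:U wobble.
    """
    pair_sum = mirna[None, :] + windows
    pen = np.where(
        pair_sum == 3, 0.0, np.where(pair_sum == 5, wobble_penalty, mismatch_penalty)
    )
    lo, hi = seed_region
    pen[:, lo - 1 : hi] *= seed_multiplier
    return pen


def score_window(
    mirna_seq: str,
    target_window: str,
    seed_region: tuple[int, int] = DEFAULT_SEED_REGION,
    wobble_penalty: float = 0.5,
    mismatch_penalty: float = 1.0,
    seed_multiplier: float = 2.0,
) -> float:
    """Penalty score of one target window (same length as the miRNA)."""
    if len(target_window) != len(mirna_seq):
        raise SequenceError(
            f"window length {len(target_window)} != miRNA length {len(mirna_seq)}"
        )
    mi = _encode(mirna_seq, "miRNA")
    win = _encode(target_window, "target window")[::-1]
    pen = _penalty_matrix(
        mi, win[None, :], seed_region, wobble_penalty, mismatch_penalty, seed_multiplier
    )
    return float(pen.sum())


def _alignment_string(mirna: np.ndarray, window_rev: np.ndarray) -> str:
    s = mirna + window_rev
    return "".join("|" if v == 3 else ("o" if v == 5 else ".") for v in s)


def scan_target(
    mirna_seq: str,
    target_seq: str,
    circular: bool = False,
    mirna_id: str = "",
    target_id: str = "",
    kind: str = "mRNA",
    seed_region: tuple[int, int] = DEFAULT_SEED_REGION,
) -> TargetHit | None:
    """Best-scoring window of one miRNA on one target.

    Slides a window of miRNA length over the target; for circular targets the
    seam windows (last L-1 bases joined to the first L-1) are scanned too.
    Ties go to the smallest start coordinate, with seam-spanning windows
    ordered after linear ones. Returns ``None`` (no hit) when the target is
    shorter than the miRNA.
    """
    L = len(mirna_seq)
    if len(target_seq) < L:
        return None
    mi = _encode(mirna_seq, "miRNA")
    tg = _encode(target_seq, "target")

    windows = sliding_window_view(tg, L)[:, ::-1]
    scores = _penalty_matrix(mi, windows, seed_region, 0.5, 1.0, 2.0).sum(axis=1)
    best_idx = int(np.argmin(scores))  # argmin takes the first = smallest start
    best_score = float(scores[best_idx])
    best_start = best_idx + 1
    best_junction = False

    if circular:
        n = len(target_seq)
        # offsets descending so starts ascend: strict < keeps the smallest start
        for offset in range(L - 1, 0, -1):  # window starts offset bases before the seam
            win_seq = target_seq[n - offset :] + target_seq[: L - offset]
            s = score_window(mirna_seq, win_seq, seed_region=seed_region)
            if s < best_score:
                best_score = s
                best_start = n - offset + 1
                best_junction = True

    win_enc = _window_at(tg, best_start, L, best_junction)
    return TargetHit(
        mirna_id=mirna_id,
        target_id=target_id,
        kind=kind,
        start=best_start,
        junction_spanning=best_junction,
        score=best_score,
        alignment=_alignment_string(mi, win_enc[::-1]),
    )


def _window_at(tg: np.ndarray, start: int, L: int, junction: bool) -> np.ndarray:
    if not junction:
        return tg[start - 1 : start - 1 + L]
    head = tg[start - 1 :]
    return np.concatenate([head, tg[: L - len(head)]])


def predict_targets(
    mirnas: dict[str, str],
    targets: dict[str, str],
    kinds: dict[str, str],
    cutoffs: dict[str, float] | None = None,
    circular_ids: set[str] | None = None,
    seed_region: tuple[int, int] = DEFAULT_SEED_REGION,
) -> list[TargetHit]:
    """All (miRNA, target) best hits at or below the cutoff for their kind.

    ``kinds`` maps each target id to ``"mRNA"`` or ``"circRNA"``;
    ``circular_ids`` marks targets whose seam windows should be scanned
    (defaults to every circRNA).
    """
    cutoffs = dict(DEFAULT_CUTOFFS if cutoffs is None else cutoffs)
    if circular_ids is None:
        circular_ids = {t for t, k in kinds.items() if k == "circRNA"}
    hits = []
    for mirna_id, mseq in mirnas.items():
        for target_id, tseq in targets.items():
            kind = kinds[target_id]
            hit = scan_target(
                mseq,
                tseq,
                circular=target_id in circular_ids,
                mirna_id=mirna_id,
                target_id=target_id,
                kind=kind,
                seed_region=seed_region,
            )
            if hit is not None and hit.score <= cutoffs[kind]:
                hits.append(hit)
    return hits


# ---------------------------------------------------------------------------
# Anti-correlation filter
# ---------------------------------------------------------------------------

def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN (undefined) when either vector is constant; raises for
    vectors shorter than 3 points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points for a rank correlation")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan
    return float(stats.spearmanr(x, y).statistic)


def anticorrelation_filter(
    hits: list[TargetHit],
    mirna_expr: pd.DataFrame,
    target_expr: pd.DataFrame,
    rho_max: float = -0.5,
) -> list[CorrelationFilterResult]:
    """Keep hits whose miRNA and target profiles satisfy ``rho <= rho_max``.

    The threshold is inclusive; an undefined rho (constant profile) or a
    missing expression profile fails the hit. Idempotent by construction: the
    decision depends only on the stored profiles. A tiny absolute guard
    (1e-9) keeps the inclusive boundary robust to floating-point error in the
    rank correlation (ranks are exact, but the normalization is not).
    """
    results = []
    for hit in hits:
        if hit.mirna_id not in mirna_expr.index or hit.target_id not in target_expr.index:
            results.append(CorrelationFilterResult(hit, math.nan, False))
            continue
        rho = spearman_rho(
            mirna_expr.loc[hit.mirna_id].to_numpy(),
            target_expr.loc[hit.target_id].to_numpy(),
        )
        passed = (not math.isnan(rho)) and rho <= rho_max + 1e-9
        results.append(CorrelationFilterResult(hit, rho, passed))
    return results
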