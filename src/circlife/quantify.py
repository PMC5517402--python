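"""Expression normalization, stage-wise fold changes and DE calling.

The time course is 14 single-library samples at two-day intervals (days 4–30
after leaf emergence), split into two overlapping developmental windows:

* growth-to-maturation (``G-to-M``), days 4–18, reference day 4;
* maturation-to-senescence (``M-to-S``), days 16–30, reference day 16.

Days 16 and 18 belong to both windows; each stage measures fold change
against its own reference day.

Expression is ``E = (n + 1) / N * 1e6`` — supporting reads plus a pseudocount,
divided by the sample's library size, scaled per million for readability (the
scale cancels in every fold change). A feature is differentially expressed in
a stage when ``|log2 FC| >= threshold`` (default 2, i.e. 4-fold) at *any*
non-reference day of the window; there are no replicates, so calling is a pure
fold-change threshold with no dispersion model or p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# Stage configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Stage:
    name: str
    days: tuple[int, ...]
    reference: int

    def __post_init__(self) -> None:
        if self.reference not in self.days:
            raise ValueError(
                f"stage {self.name}: reference day {self.reference} not a member"
            )


@dataclass(frozen=True)
class StageConfig:
    time_points: tuple[int, ...]
    stages: tuple[Stage, ...]

    def __post_init__(self) -> None:
        for st in self.stages:
            missing = set(st.days) - set(self.time_points)
            if missing:
                raise ValueError(f"stage {st.name}: days {sorted(missing)} not time points")

    @property
    def sample_labels(self) -> list[str]:
        return [day_label(d) for d in self.time_points]

    def stage(self, name: str) -> Stage:
        for st in self.stages:
            if st.name == name:
                return st
        raise KeyError(f"unknown stage {name!r}")

    @property
    def stage_names(self) -> list[str]:
        return [st.name for st in self.stages]


def day_label(day: int) -> str:
    return f"day{day:02d}"


def default_stage_config() -> StageConfig:
    """The leaf-lifespan grid: days 4–30 at 2-day intervals, two windows."""
    days = tuple(range(4, 31, 2))
    return StageConfig(
        time_points=days,
        stages=(
            Stage("G-to-M", tuple(range(4, 19, 2)), reference=4),
            Stage("M-to-S", tuple(range(16, 31, 2)), reference=16),
        ),
    )


# ---------------------------------------------------------------------------
# Normalization and fold changes
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    raw: pd.DataFrame          # feature x sample integer counts
    library_sizes: pd.Series   # per sample, > 0
    normalized: pd.DataFrame   # (n + 1) / N * 1e6, strictly positive


def normalize_expression(raw: pd.DataFrame, library_sizes: pd.Series) -> ExpressionMatrix:
    """``E = (n + 1) / N * 1e6`` per feature and sample."""
    sizes = library_sizes.reindex(raw.columns)
    if sizes.isna().any():
        missing = sizes.index[sizes.isna()][0]
        raise ValueError(f"no library size for sample {missing!r}")
    if (sizes <= 0).any():
        bad = sizes.index[sizes <= 0][0]
        raise ValueError(f"library size for sample {bad!r} must be positive")
    normalized = (raw + 1.0).div(sizes, axis=1) * 1e6
    return ExpressionMatrix(raw=raw, library_sizes=sizes.astype(float), normalized=normalized)


def log2_fold_changes(
    expr: ExpressionMatrix | pd.DataFrame, config: StageConfig, stage_name: str
) -> pd.DataFrame:
    """Per-feature ``log2(E_t / E_ref)`` over the stage's non-reference days.

    Columns are day labels in chronological order. Defined everywhere because
    normalized expression is strictly positive.
    """
    E = expr.normalized if isinstance(expr, ExpressionMatrix) else expr
    stage = config.stage(stage_name)
    ref = E[day_label(stage.reference)]
    cols = [day_label(d) for d in stage.days if d != stage.reference]
    return pd.DataFrame(
        {c: np.log2(E[c] / ref) for c in cols}, index=E.index
    )


def call_de(fc_profiles: pd.DataFrame, threshold: float = 2.0) -> pd.DataFrame:
    """Call differential expression from a stage's fold-change profile.

    A feature is DE when ``|log2 FC| >= threshold`` at any day (inclusive).
    Direction is the sign of the fold change at the day of maximum ``|FC|``;
    exact ties across days go to the latest day.

    Returns a frame with columns ``max_abs_log2fc``, ``day_of_max``,
    ``direction`` (``up``/``down``/``none`` for an all-zero profile) and
    ``is_de``.
    """
    days = list(fc_profiles.columns)
    if fc_profiles.empty:
        return pd.DataFrame(
            columns=["max_abs_log2fc", "day_of_max", "direction", "is_de"]
        ).rename_axis("feature_id")
    rows = []
    for feature, profile in fc_profiles.iterrows():
        best_day, best_abs = days[0], -1.0
        for d in days:  # chronological; >= prefers the latest tied day
            if abs(profile[d]) >= best_abs:
                best_abs = abs(profile[d])
                best_day = d
        fc = profile[best_day]
        direction = "up" if fc > 0 else ("down" if fc < 0 else "none")
        rows.append(
            {
                "feature_id": feature,
                "max_abs_log2fc": best_abs,
                "day_of_max": best_day,
                "direction": direction,
                "is_de": bool(best_abs >= threshold),
            }
        )
    return pd.DataFrame(rows).set_index("feature_id")


# ---------------------------------------------------------------------------
# Detection frequency and stage membership
# ---------------------------------------------------------------------------

@dataclass
class DetectionSummary:
    detection: pd.Series                 # samples with >= min_reads per feature
    histogram: dict[int, int]
    n_singletons: int
    pct_singletons: float
    n_gt10: int                          # strictly more than 10 samples
    pct_gt10: float
    retained: list[str]                  # detection >= min_samples
    stage_sets: dict[str, set[str]]      # detected at any day of the stage
    stage_pcts: dict[str, float]
    intersection: int
    union: int
    stage_sets_exclusive: dict[str, set[str]] = field(default_factory=dict)
    intersection_exclusive: int = 0      # overlap ignoring days shared by stages


def detection_summary(
    raw: pd.DataFrame,
    config: StageConfig,
    min_samples: int = 2,
    min_reads: int = 1,
) -> DetectionSummary:
    """Detection counts, the retained set, and per-stage Venn membership.

    "Detected" means at least ``min_reads`` supporting reads (default 1; the
    threshold is deliberately minimal). Days belonging to both stage windows
    count toward both stage sets; the ``*_exclusive`` fields re-do the overlap
    on stage-exclusive days only, to show how much of it the shared days drive.
    """
    detected = raw >= min_reads
    detection = detected.sum(axis=1)
    total = len(raw)

    histogram: dict[int, int] = {}
    for v in detection:
        histogram[int(v)] = histogram.get(int(v), 0) + 1

    n_singletons = int((detection == 1).sum())
    n_gt10 = int((detection > 10).sum())

    def pct(n: int) -> float:
        return round(100.0 * n / total, 1) if total else 0.0

    retained = [str(f) for f in detection.index[detection >= min_samples]]

    stage_sets: dict[str, set[str]] = {}
    for st in config.stages:
        cols = [day_label(d) for d in st.days]
        mask = detected[cols].any(axis=1)
        stage_sets[st.name] = {str(f) for f in raw.index[mask]}

    shared_days = set.intersection(*(set(st.days) for st in config.stages)) if len(
        config.stages
    ) > 1 else set()
    stage_sets_exclusive: dict[str, set[str]] = {}
    for st in config.stages:
        cols = [day_label(d) for d in st.days if d not in shared_days]
        mask = detected[cols].any(axis=1) if cols else pd.Series(False, index=raw.index)
        stage_sets_exclusive[st.name] = {str(f) for f in raw.index[mask]}

    sets = list(stage_sets.values())
    intersection = len(set.intersection(*sets)) if sets else 0
    union = len(set.union(*sets)) if sets else 0
    ex_sets = list(stage_sets_exclusive.values())
    intersection_exclusive = len(set.intersection(*ex_sets)) if ex_sets else 0

    return DetectionSummary(
        detection=detection,
        histogram=dict(sorted(histogram.items())),
        n_singletons=n_singletons,
        pct_singletons=pct(n_singletons),
        n_gt10=n_gt10,
        pct_gt10=pct(n_gt10),
        retained=retained,
        stage_sets=stage_sets,
        stage_pcts={k: pct(len(v)) for k, v in stage_sets.items()},
        intersection=intersection,
        union=union,
        stage_sets_exclusive=stage_sets_exclusive,
        intersection_exclusive=intersection_exclusive,
    )


# ---------------------------------------------------------------------------
# Host-gene concordance
# ---------------------------------------------------------------------------

@dataclass
class StageConcordance:
    stage: str
    n_up_circ: int
    n_concordant: int
    fraction: float
    concordant_ids: list[str]


@dataclass
class ConcordanceReport:
    per_stage: dict[str, StageConcordance]
    rho: dict[str, float]        # circ id -> Spearman rho with its host profile
    skipped: list[str]           # circRNAs without a host gene


def host_concordance(
    circ_de: dict[str, pd.DataFrame],
    gene_de: dict[str, pd.DataFrame],
    circ_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    host_map: dict[str, str],
) -> ConcordanceReport:
    """Is circRNA upregulation mirrored by the host's linear transcript?

    For every stage, counts the up-regulated DE circRNAs whose host gene is
    itself up-regulated DE under the identical normalization and threshold,
    and reports per-pair Spearman correlation between circRNA and host
    normalized profiles over the whole course. circRNAs without a host gene
    (intergenic, ambiguous) are skipped and listed.
    """
    per_stage: dict[str, StageConcordance] = {}
    skipped: list[str] = []

    for stage, cdf in circ_de.items():
        gdf = gene_de[stage]
        up_circ = [str(f) for f in cdf.index[(cdf["is_de"]) & (cdf["direction"] == "up")]]
        concordant = []
        for cid in up_circ:
            host = host_map.get(cid)
            if host is None:
                if cid not in skipped:
                    skipped.append(cid)
                continue
            if host in gdf.index and bool(
                gdf.loc[host, "is_de"] and gdf.loc[host, "direction"] == "up"
            ):
                concordant.append(cid)
        n_up = len(up_circ)
        per_stage[stage] = StageConcordance(
            stage=stage,
            n_up_circ=n_up,
            n_concordant=len(concordant),
            fraction=len(concordant) / n_up if n_up else math.nan,
            concordant_ids=concordant,
        )

    rho: dict[str, float] = {}
    for cid, host in host_map.items():
        if cid in circ_expr.normalized.index and host in gene_expr.normalized.index:
            x = circ_expr.normalized.loc[cid].to_numpy(dtype=float)
            y = gene_expr.normalized.loc[host].to_numpy(dtype=float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                rho[cid] = math.nan
            else:
                rho[cid] = float(stats.spearmanr(x, y).statistic)

    return ConcordanceReport(per_stage=per_stage, rho=rho, skipped=skipped)
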