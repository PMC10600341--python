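"""Five-phase cell-cycle scoring and classification for scRNA-seq.

The procedure mirrors the marker-fluctuation approach used to estimate cell
cycle status in germ-cell single-cell data:

1. **Reference filtering** — genes from the phase reference sets that
   correlate weakly (Pearson R below a threshold, default 0.2) with their
   own phase score are excluded.
2. **Scoring** — each cell's score for a phase is the average normalized
   expression of that phase's retained reference genes.
3. **Scaling** — scores are z-scored per phase across cells, then each
   cell's 5-vector is row-centered, yielding a per-cell *pattern* of
   phase-specific scores.
4. **Assignment** — each pattern is compared (Pearson similarity) against
   idealized phase patterns.  Cells matching G1/S or S cleanly keep those
   labels; cells whose best match lies anywhere in G2 / G2/M / M/G1 are
   collapsed into a single G2/M/G1 category, because post-S-phase
   expression patterns blend across those stages; cells with uniformly low
   scores are called G1; everything else is unclassified.

The assignment thresholds (``tau_low``, ``delta_margin``, ``sim_min``) are
interpretation parameters: the collapsed categories are part of the method,
but the exact numeric cutoffs separating G1 and unclassified are not fixed
by any published criterion, so they are explicit, recorded in provenance,
and configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats as sps

from germcycle.genesets import PHASES, PhaseGeneSets

#: The label vocabulary of the classifier.
LABELS: tuple[str, ...] = ("G1", "G1/S", "S", "G2/M/G1", "unclassified")

_LATE = ("G2", "G2/M", "M/G1")


@dataclass(frozen=True)
class AssignParams:
    """Thresholds of the pattern-assignment step.

    r_min
        Pearson correlation below which a reference gene is excluded
        (the filter step; kept here so one object carries all knobs).
    tau_low
        If every stage-1 z-scored phase score of a cell falls below this
        value the cell is called G1 (no cycling signature), provided its
        best pattern similarity passed ``sim_min``.
    delta_margin
        Similarity margin over the runner-up pattern required to keep a
        G1/S or S call; smaller margins are ambiguous.
    sim_min
        Minimum best-pattern similarity; below it a cell is unclassified.
    """

    r_min: float = 0.2
    tau_low: float = 0.0
    delta_margin: float = 0.3
    sim_min: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.r_min < 1:
            raise ValueError("r_min must be in [0, 1)")
        if not -1 <= self.sim_min <= 1:
            raise ValueError("sim_min must be in [-1, 1]")
        if self.delta_margin < 0:
            raise ValueError("delta_margin must be >= 0")


@dataclass
class ScaledScores:
    """Two-stage scaled phase scores.

    ``zscored``: stage 1, each phase column standardized across cells
    (mean 0, sd 1).  ``pattern``: stage 2, each cell's z-scored 5-vector
    additionally row-centered; this is the per-cell pattern compared against
    the idealized phase patterns.  The low-score G1 rule is evaluated on
    ``zscored`` (a row-centered vector can never be uniformly negative).
    """

    zscored: pd.DataFrame
    pattern: pd.DataFrame


def _phase_score_matrix(values: pd.DataFrame, sets: PhaseGeneSets) -> pd.DataFrame:
    cols = {}
    for phase in PHASES:
        present = [g for g in sets[phase] if g in values.columns]
        if not present:
            raise ValueError(f"phase {phase!r} has no genes in the matrix")
        cols[phase] = values[present].mean(axis=1)
    return pd.DataFrame(cols, index=values.index)[list(PHASES)]


def _expr_frame(expr: ad.AnnData) -> pd.DataFrame:
    return pd.DataFrame(
        np.asarray(expr.X, dtype=float),
        index=expr.obs_names,
        columns=expr.var_names,
    )


def filter_reference_genes(
    expr: ad.AnnData,
    sets: PhaseGeneSets,
    r_min: float = 0.2,
    method: str = "pearson",
    iterate: bool = False,
    max_iter: int = 10,
) -> PhaseGeneSets:
    """Exclude reference genes weakly correlated with their phase score.

    For each phase a provisional score is computed as the per-cell mean
    expression of the phase's genes present in the matrix (the gene under
    test included).  A gene is retained iff its correlation with its own
    phase score is at least ``r_min``; genes with undefined correlation
    (zero variance) are excluded.  Genes absent from the matrix are dropped
    with a warning.  A phase losing all genes raises :class:`ValueError`.

    With ``iterate=True`` scores are recomputed from the surviving genes
    until the retained set is stable (a sensitivity-analysis mode; the
    default is the single exclusion pass).
    """
    if expr.n_obs < 3:
        raise ValueError("need at least 3 cells to estimate correlations")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    values = _expr_frame(expr)

    absent = [g for g in sets.all_genes if g not in values.columns]
    if absent:
        warnings.warn(
            f"{len(absent)} reference genes absent from the matrix and "
            f"dropped (e.g. {absent[:5]})",
            stacklevel=2,
        )
        sets = sets.subset(values.columns)

    current = sets
    for _ in range(max_iter if iterate else 1):
        scores = _phase_score_matrix(values, current)
        keep: dict[str, tuple[str, ...]] = {}
        for phase in PHASES:
            s = scores[phase].to_numpy()
            retained = []
            for g in current[phase]:
                x = values[g].to_numpy()
                if np.std(x) == 0 or np.std(s) == 0:
                    continue  # undefined correlation -> excluded
                if method == "pearson":
                    r = sps.pearsonr(x, s).statistic
                else:
                    r = sps.spearmanr(x, s).statistic
                if r >= r_min:
                    retained.append(g)
            if not retained:
                raise ValueError(
                    f"phase {phase!r} retained no reference genes at "
                    f"r_min={r_min}"
                )
            keep[phase] = tuple(retained)
        new = PhaseGeneSets(keep)
        if new.genes == current.genes:
            break
        current = new
    return current


def compute_phase_scores(
    expr: ad.AnnData, sets: PhaseGeneSets
) -> pd.DataFrame:
    """Per-cell phase scores: mean expression of each phase's genes.

    Returns a cells x 5 DataFrame in the fixed phase order; the gene sets
    actually used are attached as ``df.attrs['retained_genes']``.
    """
    values = _expr_frame(expr)
    missing = [g for g in sets.all_genes if g not in values.columns]
    if missing:
        raise ValueError(
            f"{len(missing)} reference genes missing from the matrix; "
            "run filter_reference_genes first"
        )
    scores = _phase_score_matrix(values, sets)
    scores.attrs["retained_genes"] = sets.sizes()
    return scores


def scale_scores(scores: pd.DataFrame) -> ScaledScores:
    """Standardize scores per phase, then center each cell's 5-vector.

    Stage 1 z-scores each phase column (population sd); a zero-variance
    column raises :class:`ValueError` naming the phase.  Stage 2 subtracts
    each cell's row mean, turning absolute scores into a relative pattern.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 cells to scale scores")
    arr = scores.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"phase column {scores.columns[dead[0]]!r} has zero variance"
        )
    z = (arr - arr.mean(axis=0)) / sd
    pattern = z - z.mean(axis=1, keepdims=True)
    idx, cols = scores.index, scores.columns
    return ScaledScores(
        zscored=pd.DataFrame(z, index=idx, columns=cols),
        pattern=pd.DataFrame(pattern, index=idx, columns=cols),
    )


def ideal_phase_patterns() -> pd.DataFrame:
    """Idealized row-centered phase patterns (5 phases x 5 scores).

    Phase k expects a peak (1) at its own score, shoulders (0.5) at the two
    cyclically adjacent phases (order G1/S -> S -> G2 -> G2/M -> M/G1 ->
    G1/S) and 0 elsewhere, then row-centering — encoding the persistence of
    phase programs into neighbouring stages.
    """
    n = len(PHASES)
    m = np.zeros((n, n))
    for k in range(n):
        m[k, k] = 1.0
        m[k, (k - 1) % n] = 0.5
        m[k, (k + 1) % n] = 0.5
    m -= m.mean(axis=1, keepdims=True)
    return pd.DataFrame(m, index=PHASES, columns=PHASES)


def _row_normalize(arr: np.ndarray) -> np.ndarray:
    centered = arr - arr.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norms > 0, centered / norms, 0.0)
    return out


def assign_phase(
    scaled: ScaledScores,
    params: AssignParams = AssignParams(),
    patterns: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assign each cell a cell-cycle label from its score pattern.

    Decision per cell, in order:

    1. similarity = Pearson correlation of the cell pattern with each
       idealized phase pattern; ``best_phase`` is the argmax (ties broken by
       the fixed phase order);
    2. best similarity < ``sim_min`` -> ``unclassified``;
    3. all five stage-1 z-scores < ``tau_low`` -> ``G1``;
    4. best phase G1/S or S with similarity margin >= ``delta_margin`` over
       the runner-up -> that phase;
    5. best phase in G2 / G2/M / M/G1 -> ``G2/M/G1``;
    6. otherwise -> ``unclassified``.

    Returns a DataFrame with ``label``, ``best_phase`` and ``similarity``.
    """
    if patterns is None:
        patterns = ideal_phase_patterns()
    P = _row_normalize(scaled.pattern.to_numpy(dtype=float))
    I = _row_normalize(patterns.to_numpy(dtype=float))
    sim = P @ I.T  # cells x phases Pearson similarity

    best_idx = sim.argmax(axis=1)  # argmax keeps first (fixed phase order)
    order = np.sort(sim, axis=1)
    best, second = order[:, -1], order[:, -2]
    margin = best - second
    z = scaled.zscored.to_numpy(dtype=float)

    phase_names = np.array(patterns.index)
    best_phase = phase_names[best_idx]
    labels = np.full(len(P), "unclassified", dtype=object)

    low_all = (z < params.tau_low).all(axis=1)
    passed = best >= params.sim_min
    early = np.isin(best_phase, ("G1/S", "S"))
    late = np.isin(best_phase, _LATE)

    labels[passed & late] = "G2/M/G1"
    keep_early = passed & early & (margin >= params.delta_margin)
    labels[keep_early] = best_phase[keep_early]
    labels[passed & low_all] = "G1"

    out = pd.DataFrame(
        {
            "label": pd.Categorical(labels, categories=LABELS),
            "best_phase": best_phase,
            "similarity": best,
        },
        index=scaled.pattern.index,
    )
    out.attrs["params"] = vars(params).copy()
    return out


def score_and_assign(
    expr: ad.AnnData,
    sets: PhaseGeneSets,
    params: AssignParams = AssignParams(),
) -> pd.DataFrame:
    """Full scoring pipeline: filter -> score -> scale -> assign.

    Returns the assignment DataFrame augmented with the raw and scaled
    scores (columns ``score_*`` and ``z_*``).
    """
    retained = filter_reference_genes(expr, sets, r_min=params.r_min)
    scores = compute_phase_scores(expr, retained)
    scaled = scale_scores(scores)
    labels = assign_phase(scaled, params)
    for phase in PHASES:
        labels[f"score_{phase}"] = scores[phase]
        labels[f"z_{phase}"] = scaled.zscored[phase]
    return labels


def phase_proportions(
    labels: Sequence[str] | pd.Series,
    group: Sequence[str] | pd.Series,
) -> pd.DataFrame:
    """Per-group label counts and proportions.

    Returns a DataFrame indexed by group with one count column and one
    proportion column per label category; proportions sum to 1 per group.
    """
    df = pd.DataFrame({
        "label": pd.Categorical(labels, categories=LABELS),
        "group": list(group),
    })
    counts = df.groupby("group", observed=False)["label"].value_counts().unstack()
    counts = counts.reindex(columns=LABELS, fill_value=0)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        empty = totals.index[totals == 0].tolist()
        raise ValueError(f"empty group(s): {empty}")
    props = counts.div(totals, axis=0)
    out = pd.concat(
        [counts.add_prefix("n_"), props.add_prefix("prop_")], axis=1
    )
    out["n_total"] = totals
    return out


def compare_proportions(table: pd.DataFrame) -> tuple[float, int, float]:
    """Chi-square test of homogeneity of label composition across groups.

    ``table`` is a proportions table from :func:`phase_proportions` (its
    ``n_<label>`` columns are used) or a raw group x label count frame.
    Label categories with zero counts in every group are dropped.  Returns
    ``(statistic, dof, p_value)``; no continuity correction is applied.
    """
    count_cols = [c for c in table.columns if c.startswith("n_") and c != "n_total"]
    counts = table[count_cols] if count_cols else table
    counts = counts.loc[counts.sum(axis=1) > 0]
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 non-empty groups")
    counts = counts.loc[:, counts.sum(axis=0) > 0]
    res = sps.chi2_contingency(counts.to_numpy(), correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)
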