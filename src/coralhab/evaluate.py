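"""Model evaluation: partitioning, presence-background AUC, test gain,
percentile thresholding, omission, significance and covariate screening.

Presence-background AUC is the probability that a presence cell is scored
above a random background cell (ties count one half) — the rank/Mann-
Whitney formulation, invariant under any strictly monotone transform of
the scores.  0.5 means no better than random; 1 is the maximum.

Test gain is the mean log likelihood-ratio of the test presences against a
uniform distribution over the background: a gain of 2 means a test
presence is exp(2) (about 7.4) times more likely than a random background
cell.

The suitability threshold is the 10th percentile of training-presence
scores (linear interpolation between order statistics), under the
assumption that up to 10% of presences may be mis-positioned; the omission
rate is the fraction of (test) presences scoring strictly below it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grid import LayerStack
from .maxent import JackknifeRow, NicheModel
from .presences import PresenceSet

__all__ = [
    "Partition",
    "EvaluationReport",
    "partition",
    "auc_presence_background",
    "test_gain",
    "gain_likelihood_ratio",
    "percentile_threshold",
    "omission_rate",
    "auc_significance",
    "covariation_screen",
    "niche_summary",
    "evaluate_species",
]

log = logging.getLogger(__name__)

CORRELATION_FLAG = 0.7
DEFAULT_TRAIN_FRACTION = 0.7
DEFAULT_THRESHOLD_PERCENTILE = 10.0


@dataclass
class Partition:
    """A random train/test split of a presence set."""

    train: PresenceSet
    test: PresenceSet
    fraction_train: float
    seed: int


@dataclass
class EvaluationReport:
    """Validation statistics for one species run."""

    species: str
    n_train: int
    n_test: int
    test_auc: float
    test_auc_sd: float
    test_gain: float
    threshold_10pct: float
    omission_rate: float
    training_omission_rate: float
    wilcoxon_p: float
    full_gain: float
    jackknife: list[JackknifeRow] = field(default_factory=list)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(validation-statistics frame, jack-knife frame)."""
        rows = [
            ("Test AUC", self.test_auc),
            ("Test AUC SD", self.test_auc_sd),
            ("Test gain", self.test_gain),
            ("10th percentile training presence", self.threshold_10pct),
            ("Omission rate", self.omission_rate),
            ("Training omission rate", self.training_omission_rate),
            ("Wilcoxon p (AUC vs 0.5)", self.wilcoxon_p),
            ("Training gain (full model)", self.full_gain),
        ]
        stat = pd.DataFrame(rows, columns=["statistic", "value"])
        stat.insert(0, "species", self.species)
        if self.jackknife:
            jk = pd.DataFrame(
                [
                    (self.species, r.variable, r.gain_without, r.gain_only, r.test_auc_only)
                    for r in self.jackknife
                ],
                columns=["species", "variable", "gain_without", "gain_only", "test_auc_only"],
            )
            return stat, jk
        return stat, pd.DataFrame(
            columns=["species", "variable", "gain_without", "gain_only", "test_auc_only"]
        )


def partition(pset: PresenceSet, fraction_train: float, seed: int) -> Partition:
    """Seeded uniform random 70/30-style split; train size is
    round(fraction * n)."""
    n = len(pset)
    if n < 4:
        raise ValueError("need at least 4 presences to partition")
    if not 0 < fraction_train < 1:
        raise ValueError("fraction_train must be strictly between 0 and 1")
    n_train = int(round(fraction_train * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_idx = np.sort(order[:n_train])
    test_idx = np.sort(order[n_train:])
    train = PresenceSet(
        pset.species, [pset.records[i] for i in train_idx], pset.reference_geotransform
    )
    test = PresenceSet(
        pset.species, [pset.records[i] for i in test_idx], pset.reference_geotransform
    )
    return Partition(train, test, fraction_train, seed)


def auc_presence_background(presence_scores, background_scores) -> float:
    """Mann-Whitney AUC: fraction of (presence, background) pairs with the
    presence ranked higher; ties count 1/2."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("score lists must be nonempty")
    ranks = stats.rankdata(np.concatenate([p, b]))
    r_p = ranks[: p.size].sum()
    u = r_p - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


def test_gain(
    model: NicheModel, test_presences: np.ndarray, background: np.ndarray
) -> float:
    """Mean log likelihood-ratio of test presences vs a uniform background
    cell: mean(log(q(x) * N_background)).  0 for the uniform model."""
    test_presences = np.atleast_2d(np.asarray(test_presences, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if test_presences.size == 0 or background.size == 0:
        raise ValueError("nonempty inputs required")
    logq = model.log_density(test_presences)
    floor = -745.0  # log of the smallest positive double
    if np.any(logq < floor):
        log.warning("test_gain: clamping %d zero-density test points", int((logq < floor).sum()))
        logq = np.maximum(logq, floor)
    return float(np.mean(logq + np.log(background.shape[0])))


def gain_likelihood_ratio(gain: float) -> float:
    """Interpretation helper: exp(gain) is how many times more likely a
    test presence is than a random background cell (gain 2 -> ~7.4)."""
    return float(np.exp(gain))


def percentile_threshold(training_scores, percentile: float = DEFAULT_THRESHOLD_PERCENTILE) -> float:
    """Score at the given percentile of training-presence scores, with
    linear interpolation between order statistics."""
    s = np.asarray(training_scores, dtype=float)
    if s.size == 0:
        raise ValueError("training_scores must be nonempty")
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    return float(np.percentile(s, percentile, method="linear"))


def omission_rate(test_scores, threshold: float) -> float:
    """Fraction of test scores strictly below the threshold (a presence
    exactly at the threshold is predicted present, matching the >= rule of
    the binary map)."""
    s = np.asarray(test_scores, dtype=float)
    if s.size == 0:
        raise ValueError("test_scores must be nonempty")
    return float(np.mean(s < threshold))


def auc_significance(test_auc_replicates, null_auc_replicates) -> float:
    """Two-sided Wilcoxon rank-sum p-value comparing replicate test AUCs
    against matched null-model AUCs (label-permuted scoring)."""
    a = np.asarray(test_auc_replicates, dtype=float)
    b = np.asarray(null_auc_replicates, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("need at least 5 replicates per group")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.pvalue)


def evaluate_species(
    pset: PresenceSet,
    stack: LayerStack,
    maxent_config=None,
    fraction_train: float = DEFAULT_TRAIN_FRACTION,
    percentile: float = DEFAULT_THRESHOLD_PERCENTILE,
    n_replicates: int = 10,
    seed: int = 0,
    with_jackknife: bool = True,
) -> EvaluationReport:
    """Full evaluation of one species run.

    Repeats the 70/30-style partition ``n_replicates`` times with derived
    seeds, refitting each time; the reported test AUC is the replicate
    mean with its SD (the parenthetical of a validation table).  Gain,
    threshold, omission and the jack-knife come from the first replicate.
    Significance against a random (AUC 0.5) prediction uses matched
    label-permuted null AUCs per replicate.
    """
    from .maxent import MaxentConfig, fit, jackknife as jk_fn, sample_background

    maxent_config = maxent_config or MaxentConfig(seed=seed)
    background = sample_background(stack, maxent_config)
    ref = stack.reference
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2 ** 31)
    aucs, null_aucs = [], []
    first = {}
    for r, s in enumerate(seeds):
        part = partition(pset, fraction_train, int(s))
        tr_rows, tr_cols = part.train.cell_indices(ref)
        te_rows, te_cols = part.test.cell_indices(ref)
        X_train = stack.covariates_at_cells(tr_rows, tr_cols)
        X_test = stack.covariates_at_cells(te_rows, te_cols)
        model = fit(X_train, background, maxent_config, stack.names)
        test_scores = model.hsi(X_test)
        bg_scores = model.hsi(background)
        aucs.append(auc_presence_background(test_scores, bg_scores))
        # matched null: same scores, presence/background labels permuted
        pool = np.concatenate([test_scores, bg_scores])
        rng = np.random.default_rng(int(s) + 1)
        perm = rng.permutation(pool.size)
        null_aucs.append(
            auc_presence_background(
                pool[perm[: test_scores.size]], pool[perm[test_scores.size:]]
            )
        )
        if r == 0:
            train_scores = model.hsi(X_train)
            thr = percentile_threshold(train_scores, percentile)
            first = {
                "model": model,
                "n_train": len(part.train),
                "n_test": len(part.test),
                "gain": test_gain(model, X_test, background),
                "thr": thr,
                "omission": omission_rate(test_scores, thr),
                "train_omission": omission_rate(train_scores, thr),
                "X_train": X_train,
                "X_test": X_test,
            }
    rows: list[JackknifeRow] = []
    if with_jackknife:
        rows, _full_gain = jk_fn(
            first["X_train"], background, stack.names, maxent_config, first["X_test"]
        )
    return EvaluationReport(
        species=pset.species,
        n_train=first["n_train"],
        n_test=first["n_test"],
        test_auc=float(np.mean(aucs)),
        test_auc_sd=float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0,
        test_gain=first["gain"],
        threshold_10pct=first["thr"],
        omission_rate=first["omission"],
        training_omission_rate=first["train_omission"],
        wilcoxon_p=auc_significance(aucs, null_aucs) if len(aucs) >= 5 else np.nan,
        full_gain=first["model"].training_gain,
        jackknife=rows,
    )


def covariation_screen(
    stack: LayerStack, n_points: int = 10_000, seed: int = 0
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pairwise Pearson correlations over seeded random valid cells.

    Pairs with |r| above the 0.7 flag level are reported, not auto-dropped:
    a strongly correlated pair may still both be retained on the strength
    of their individual contributions (as temperature and aragonite
    saturation were in the reference analysis).  Zero-variance layers give
    undefined (NaN) correlations and are flagged.
    """
    if len(stack) < 2:
        raise ValueError("covariation_screen needs at least 2 layers")
    rows, cols = stack.valid_cells()
    if rows.size == 0:
        raise ValueError("no valid cells")
    rng = np.random.default_rng(seed)
    n = min(n_points, rows.size)
    sel = rng.choice(rows.size, size=n, replace=False)
    X = stack.covariates_at_cells(rows[sel], cols[sel])
    names = stack.names
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(X, rowvar=False)
    df = pd.DataFrame(corr, index=names, columns=names)
    flags = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = corr[i, j]
            if np.isnan(r) or abs(r) > CORRELATION_FLAG:
                flags.append((names[i], names[j], float(r)))
    return df, flags


def niche_summary(
    pset: PresenceSet,
    stack: LayerStack,
    exceedance: dict[str, tuple[str, float]] | None = None,
) -> pd.DataFrame:
    """Per-variable summary of conditions at presence cells.

    Returns mean, SD, min, max of each layer sampled at the presences,
    plus optional threshold-exceedance percentages, e.g.
    ``{"aragonite": (">", 1.0), "depth": ("<", 1500.0)}`` reports the
    percentage of presences in supersaturated water and shallower than
    1500 m.
    """
    if len(pset) == 0:
        raise ValueError("empty presence set")
    rows, cols = pset.cell_indices(stack.reference)
    X = stack.covariates_at_cells(rows, cols)
    exceedance = exceedance or {}
    out = []
    for j, name in enumerate(stack.names):
        v = X[:, j]
        v = v[np.isfinite(v)]
        row = {
            "variable": name,
            "n": int(v.size),
            "mean": float(np.mean(v)) if v.size else np.nan,
            "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
            "min": float(np.min(v)) if v.size else np.nan,
            "max": float(np.max(v)) if v.size else np.nan,
        }
        if name in exceedance:
            op, thr = exceedance[name]
            if op not in ("<", ">", "<=", ">="):
                raise ValueError(f"unsupported exceedance operator {op!r}")
            frac = {
                "<": np.mean(v < thr),
                ">": np.mean(v > thr),
                "<=": np.mean(v <= thr),
                ">=": np.mean(v >= thr),
            }[op] if v.size else np.nan
            row["exceedance"] = f"{op}{thr}"
            row["exceedance_pct"] = float(100.0 * frac)
        out.append(row)
    return pd.DataFrame(out)
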