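"""Position-level pausing outliers against flow-model expectations.

The outlier strength at (m, k) is the observed transformed count minus the
expected count J_m * mu_m^c, divided by a noise scale s_mk that captures the
count variance attributable to the gene's abundance and the codon identity:
genes are split into abundance quantile bins (32 by default) and s is the
sample standard deviation of transformed counts within each (bin, codon)
cell.  Positions with strength above a threshold T are slow outliers;
positions with strength strictly inside (-1, 1) are non-outliers.  Apparent
fast outliers are excluded from comparisons because A-site assignment
uncertainty can misattribute fragments away from a position, deflating its
count, whereas a large excess of counts is unlikely to be artifactual.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from riboflow.flowmodel import ModelFit, TransformedCounts

__all__ = [
    "NoiseBins", "OutlierCall", "DEFAULT_THRESHOLDS",
    "fit_noise_bins", "outlier_strength", "outlier_table",
    "classify_outliers", "feature_significance", "ks_position_test",
]

DEFAULT_THRESHOLDS = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5)


@dataclasses.dataclass
class NoiseBins:
    """Abundance-binned, codon-stratified noise scales s_mk.

    ``sd[(bin, codon)]`` is the ddof=1 standard deviation of transformed
    counts for the codon within the abundance bin; every cell has at least
    three observations and strictly positive sd.  ``n_bins`` may be lower
    than requested if the requested binning was infeasible.
    """

    n_bins: int
    bin_edges: np.ndarray
    gene_bin: dict[str, int]
    sd: dict[tuple[int, str], float]
    requested_bins: int = 32

    def lookup(self, gene: str, codon: str) -> float:
        return self.sd[(self.gene_bin[gene], codon)]


@dataclasses.dataclass(frozen=True)
class OutlierCall:
    gene: str
    position: int
    delta: float
    klass: str  # "slow" | "non_outlier" | "excluded"


def _try_bins(
    abundance: pd.Series,
    obs: pd.DataFrame,
    n_bins: int,
) -> dict | None:
    """Attempt an n_bins quantile binning; None if any (bin, codon) cell has
    fewer than 3 observations or zero sd."""
    try:
        bins, edges = pd.qcut(
            abundance, n_bins, labels=False, retbins=True, duplicates="raise"
        )
    except ValueError:
        return None
    gene_bin = dict(zip(abundance.index, bins.astype(int)))
    obs = obs.assign(bin=obs["gene"].map(gene_bin))
    sd: dict[tuple[int, str], float] = {}
    for (b, c), grp in obs.groupby(["bin", "codon"], sort=True):
        if len(grp) < 3:
            return None
        s = float(np.std(grp["value"].to_numpy(), ddof=1))
        if not (s > 0):
            return None
        sd[(int(b), str(c))] = s
    return {"edges": edges, "gene_bin": gene_bin, "sd": sd}


def fit_noise_bins(
    tc: TransformedCounts,
    n_bins: int = 32,
) -> NoiseBins:
    """Estimate s_mk from transformed counts.

    Genes are binned into ``n_bins`` abundance quantiles (abundance = the
    mean raw footprint count D_m); per (bin, codon) cell the ddof=1 standard
    deviation of d' is computed.  If any cell has fewer than three counts or
    zero sd, n_bins is reduced to the maximum feasible value (recorded on
    the result); no feasible binning at all is an error.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if tc.codons is None:
        raise ValueError("TransformedCounts lacks codon identities")
    rows = []
    for g, dp in tc.dprime.items():
        if g not in tc.codons:
            continue
        cods = tc.codons[g]
        # observed counts on the outlier axis: pseudo-counted raw counts
        # times the single global scale (flow normalization undone)
        obs_counts = dp * tc.gene_mean[g]
        for k in range(dp.size):
            rows.append((g, cods[k], obs_counts[k]))
    obs = pd.DataFrame(rows, columns=["gene", "codon", "value"])
    abundance = pd.Series(
        {g: tc.gene_mean[g] for g in tc.dprime if g in (tc.codons or {})}
    )
    for nb in range(n_bins, 0, -1):
        res = _try_bins(abundance, obs, nb)
        if res is not None:
            if nb < n_bins:
                warnings.warn(
                    f"reduced abundance bins from {n_bins} to {nb} to keep "
                    ">=3 counts and nonzero sd per (bin, codon) cell"
                )
            return NoiseBins(
                n_bins=nb, bin_edges=np.asarray(res["edges"]),
                gene_bin=res["gene_bin"], sd=res["sd"], requested_bins=n_bins,
            )
    raise ValueError("no feasible abundance binning, even with a single bin")


def outlier_strength(dprime: float, J: float, mu: float, s: float) -> float:
    """Delta = (observed - expected) / noise scale, on the transformed axis."""
    if not (s > 0):
        raise ValueError("noise scale s must be positive")
    return (dprime - J * mu) / s


def outlier_table(
    tc: TransformedCounts,
    fit: ModelFit,
    noise: NoiseBins,
) -> pd.DataFrame:
    """Per-position outlier strengths for every profiled position.

    Returns a DataFrame with columns gene, position, codon, delta.  Expected
    counts use the gene's fitted flow and per-gene codon dwell, falling back
    to the global dwell outside the restricted region.
    """
    recs = []
    for g, dp in tc.dprime.items():
        if g not in (tc.codons or {}):
            continue
        cods = tc.codons[g]
        J = fit.J[g]
        obs = dp * tc.gene_mean[g]  # scaled pseudo counts, same axis as J
        for k in range(dp.size):
            c = cods[k]
            mu = fit.mu_gene.get((g, c), fit.mu_global.get(c))
            if mu is None:
                continue
            s = noise.lookup(g, c)
            recs.append((g, k, c, (obs[k] - J * mu) / s))
    return pd.DataFrame(recs, columns=["gene", "position", "codon", "delta"])


def classify_outliers(
    deltas: pd.DataFrame,
    T: float = 1.0,
) -> list[OutlierCall]:
    """Classify positions: slow if delta > T; non-outlier if -1 < delta < 1
    (and not slow); everything else excluded."""
    calls = []
    for row in deltas.itertuples():
        d = float(row.delta)
        if d > T:
            klass = "slow"
        elif -1.0 < d < 1.0:
            klass = "non_outlier"
        else:
            klass = "excluded"
        calls.append(OutlierCall(str(row.gene), int(row.position), d, klass))
    return calls


def _corr_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    pr = sps.pearsonr(x, y)
    sr = sps.spearmanr(x, y)
    return float(pr.statistic), float(pr.pvalue), float(sr.statistic), float(sr.pvalue)


def feature_significance(
    feature: Mapping[tuple[str, int], float],
    deltas: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    alpha: float = 0.05,
    min_significant_codons: int = 30,
) -> dict:
    """Evaluate a candidate per-position feature against outlier strength.

    The feature is called significant only if (a) Pearson and Spearman
    correlations with delta among slow outliers share one sign and are
    significant at every threshold; (b) the per-codon-binned correlation is
    significant for at least ``min_significant_codons`` codons; and (c) the
    correlation sign matches the direction of the slow-versus-non-outlier
    mean comparison of the feature.

    Returns a dict with the overall verdict and all three sub-results.
    """
    df = deltas.copy()
    df["feat"] = [
        feature[(g, k)] for g, k in zip(df["gene"], df["position"])
    ]
    per_threshold = []
    signs: list[float] = []
    all_ok = True
    for T in thresholds:
        slow = df[df["delta"] > T]
        if len(slow) < 2:
            return {"verdict": "insufficient data", "threshold": T,
                    "per_threshold": per_threshold}
        pear_r, pear_p, spear_r, spear_p = _corr_with_p(
            slow["feat"].to_numpy(), slow["delta"].to_numpy()
        )
        ok = (
            pear_p < alpha and spear_p < alpha
            and np.sign(pear_r) == np.sign(spear_r) != 0
        )
        per_threshold.append(
            {"T": T, "pearson_r": pear_r, "pearson_p": pear_p,
             "spearman_r": spear_r, "spearman_p": spear_p, "significant": ok}
        )
        signs.append(np.sign(spear_r))
        all_ok &= ok
    consistent_sign = len(set(signs)) == 1 and signs[0] != 0
    crit_a = all_ok and consistent_sign

    # (b) correlation binned by codon, at the loosest threshold
    slow0 = df[df["delta"] > thresholds[0]]
    n_sig_codons = 0
    for _c, grp in slow0.groupby("codon"):
        if len(grp) < 3:
            continue
        r, p = sps.spearmanr(grp["feat"], grp["delta"])
        if p < alpha and np.sign(r) == signs[0]:
            n_sig_codons += 1
    crit_b = n_sig_codons >= min_significant_codons

    # (c) direction of slow vs non-outlier mean comparison
    slow1 = df[df["delta"] > thresholds[0]]
    non = df[(df["delta"] > -1) & (df["delta"] < 1) & ~(df["delta"] > thresholds[0])]
    mean_dir = np.sign(slow1["feat"].mean() - non["feat"].mean())
    crit_c = mean_dir == signs[0]

    verdict = "significant" if (crit_a and crit_b and crit_c) else "not significant"
    return {
        "verdict": verdict,
        "sign": float(signs[0]) if consistent_sign else 0.0,
        "per_threshold": per_threshold,
        "n_significant_codons": n_sig_codons,
        "mean_comparison_sign": float(mean_dir),
        "criteria": {"correlations": bool(crit_a), "codon_bins": bool(crit_b),
                     "mean_direction": bool(crit_c)},
    }


def ks_position_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test on relative outlier positions
    (k / L_m) between two gene groups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    res = sps.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)


def position_features(
    tc: TransformedCounts,
) -> dict[str, dict[tuple[str, int], float]]:
    """Built-in positional features: distance from 5' end (k), relative
    position (k / L_m), and distance from 3' end (L_m - k)."""
    from_5: dict[tuple[str, int], float] = {}
    rel: dict[tuple[str, int], float] = {}
    from_3: dict[tuple[str, int], float] = {}
    for g, dp in tc.dprime.items():
        L = dp.size
        for k in range(L):
            from_5[(g, k)] = float(k)
            rel[(g, k)] = k / L
            from_3[(g, k)] = float(L - k)
    return {"position_from_5": from_5, "position_per_length": rel,
            "position_from_3": from_3}
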