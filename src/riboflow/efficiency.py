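"""Translation efficiency and mutant-versus-wild-type comparisons.

TE_m is the model-derived protein synthesis rate J_m divided by the mRNA
abundance M_m.  Sample comparisons rank genes by the magnitude of the log
TE ratio, count how many of the top deviators lost versus gained efficiency
in the mutant, and assess the imbalance by permuting the mutant TE values
across genes.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from riboflow.ioformats import GeneRecord

__all__ = [
    "compute_te", "per_codon_te_correlation",
    "top_deviating_counts", "te_permutation_test",
]


def compute_te(J: Mapping[str, float], M: Mapping[str, float]) -> dict[str, float]:
    """TE_m = J_m / M_m over the genes shared by both tables.

    Genes with non-positive mRNA abundance are skipped with a warning.
    """
    te: dict[str, float] = {}
    skipped = []
    for g in J:
        if g not in M:
            continue
        if M[g] <= 0:
            skipped.append(g)
            continue
        te[g] = J[g] / M[g]
    if skipped:
        warnings.warn(f"skipped {len(skipped)} genes with non-positive mRNA abundance")
    return te


def _shared_genes(te_wt: Mapping[str, float], te_mut: Mapping[str, float]) -> list[str]:
    return sorted(set(te_wt) & set(te_mut))


def per_codon_te_correlation(
    te_wt: Mapping[str, float],
    te_mut: Mapping[str, float],
    genes: Mapping[str, GeneRecord],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-codon Spearman correlation between the mutant/wild-type TE ratio
    and the fraction of that codon among each gene's codons.

    Returns one row per sense codon observed, with columns codon, rho, p,
    significant.  Undefined correlations (constant ratios) are reported as
    NaN with significant=False.
    """
    shared = [g for g in _shared_genes(te_wt, te_mut) if g in genes]
    if len(shared) < 10:
        raise ValueError("need at least 10 shared genes")
    ratio = np.array([te_mut[g] / te_wt[g] for g in shared])
    frac: dict[str, np.ndarray] = {}
    for i, g in enumerate(shared):
        cods = genes[g].codons
        L = len(cods)
        vc = pd.Series(cods).value_counts()
        for c, n in vc.items():
            frac.setdefault(c, np.zeros(len(shared)))[i] = n / L
    rows = []
    constant_ratio = np.allclose(ratio, ratio[0])
    for c in sorted(frac):
        if constant_ratio or np.allclose(frac[c], frac[c][0]):
            rows.append((c, np.nan, np.nan, False))
            continue
        rho, p = sps.spearmanr(ratio, frac[c])
        rows.append((c, float(rho), float(p), bool(p < alpha)))
    return pd.DataFrame(rows, columns=["codon", "rho", "p", "significant"])


def top_deviating_counts(
    te_wt: Mapping[str, float],
    te_mut: Mapping[str, float],
    n: int = 200,
) -> tuple[int, int]:
    """Among the n genes deviating most in TE (by |log ratio|), count genes
    with reduced versus increased mutant TE.  Ties at rank n are broken by
    gene id for determinism."""
    shared = _shared_genes(te_wt, te_mut)
    if n > len(shared):
        raise ValueError(f"n={n} exceeds the {len(shared)} shared genes")
    lr = np.array([np.log(te_mut[g] / te_wt[g]) for g in shared])
    order = sorted(range(len(shared)), key=lambda i: (-abs(lr[i]), shared[i]))
    top = order[:n]
    reduced = int(np.sum(lr[top] < 0))
    return reduced, n - reduced


def te_permutation_test(
    te_wt: Mapping[str, float],
    te_mut: Mapping[str, float],
    n: int = 200,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Permutation test for the reduced-versus-increased imbalance.

    Mutant TE values are permuted across genes ``n_perm`` times; each time
    the (reduced - increased) difference among the top-n deviators is
    recomputed.  Returns the one-sided p (fraction of permutations with a
    difference >= observed) along with the count of permutations whose
    difference fell below the observed one.
    """
    shared = _shared_genes(te_wt, te_mut)
    if n > len(shared):
        raise ValueError(f"n={n} exceeds the {len(shared)} shared genes")
    log_wt = np.log(np.array([te_wt[g] for g in shared]))
    log_mut = np.log(np.array([te_mut[g] for g in shared]))

    def diff_for(lmut: np.ndarray) -> np.ndarray:
        # lmut: (B, n_genes) log mutant TE; vectorized top-n |log ratio|
        lr = lmut - log_wt[None, :]
        idx = np.argpartition(-np.abs(lr), n - 1, axis=1)[:, :n]
        sel = np.take_along_axis(lr, idx, axis=1)
        reduced = np.sum(sel < 0, axis=1)
        return 2 * reduced - n  # reduced - increased

    observed = int(diff_for(log_mut[None, :])[0])
    rng = np.random.default_rng(seed)
    n_genes = len(shared)
    diffs = np.empty(n_perm, dtype=np.int64)
    chunk = max(1, min(n_perm, 500))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = np.empty((b, n_genes), dtype=np.float64)
        for i in range(b):
            perms[i] = log_mut[rng.permutation(n_genes)]
        diffs[done:done + b] = diff_for(perms)
        done += b
    p_ge = float(np.mean(diffs >= observed))
    return {
        "observed_diff": observed,
        "p_value": p_ge,
        "n_perm_below_observed": int(np.sum(diffs < observed)),
        "n_perm": n_perm,
    }
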