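"""Synthetic data with known ground truth for every analysis step.

The generator states a world mirroring the model's own assumptions: genes
with configurable length and codon-usage distributions; global codon dwell
times with log-normal spread and per-gene dwells varying log-normally
around them (sigma 0.2 by default, mirroring the soft-constraint
structure); per-gene fluxes and mRNA abundances; Poisson-sampled footprint
counts d_mk ~ Poisson(depth * J_m * mu_m^c * pause_fold); optional injected
pause sites; TE datasets with a planted Kozak-motif effect; and DMS-like
count tracks with a planted accessibility profile.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from riboflow.ioformats import (
    STOP_CODONS, SENSE_CODONS, FootprintProfile, GeneRecord,
)
from riboflow.kozak_te import BASES, KozakWeights, kozak_feature

__all__ = [
    "SimTruth", "simulate_genome", "simulate_dwells", "simulate_footprints",
    "simulate_te_dataset", "simulate_dms_counts", "planted_motif",
]


@dataclasses.dataclass
class SimTruth:
    """Ground truth for a simulated footprint dataset."""

    genes: dict[str, GeneRecord]
    mu_global: dict[str, float]
    mu_gene: dict[tuple[str, str], float]
    J: dict[str, float]
    mrna_abundance: dict[str, float]
    pause_sites: list[tuple[str, int, float]]
    seed: int


def simulate_genome(
    n_genes: int,
    mean_length: int = 300,
    codon_bias: dict[str, float] | None = None,
    seed: int = 0,
    min_length: int = 20,
    utr_length: int = 30,
) -> dict[str, GeneRecord]:
    """Generate valid genes: ATG start, no internal stop, a stop at the end.

    Lengths (sense codons) are geometric-like around ``mean_length``
    (uniform in [0.5, 1.5] * mean, floored at ``min_length``); body codons
    are drawn from ``codon_bias``, a distribution over the 61 sense codons
    (uniform by default).  Random UTRs of ``utr_length`` nt provide Kozak
    contexts.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    if codon_bias is None:
        codon_bias = {c: 1.0 / len(SENSE_CODONS) for c in SENSE_CODONS}
    codons = sorted(codon_bias)
    if any(c in STOP_CODONS for c in codons):
        raise ValueError("codon bias must not put mass on stop codons")
    p = np.array([codon_bias[c] for c in codons], dtype=float)
    if np.any(p < 0) or p.sum() <= 0:
        raise ValueError("codon bias must be a distribution over sense codons")
    p = p / p.sum()
    genes: dict[str, GeneRecord] = {}
    for i in range(n_genes):
        L = max(min_length, int(rng.uniform(0.5, 1.5) * mean_length))
        body = rng.choice(codons, size=L - 1, p=p)
        cds = "ATG" + "".join(body) + str(rng.choice(("TAA", "TAG", "TGA")))
        utr5 = "".join(rng.choice(list(BASES), size=utr_length))
        utr3 = "".join(rng.choice(list(BASES), size=utr_length))
        genes[f"g{i:04d}"] = GeneRecord(f"g{i:04d}", cds, utr5, utr3)
    return genes


def simulate_dwells(
    genes: dict[str, GeneRecord],
    sigma_log_global: float = 0.5,
    sigma_log_gene: float = 0.2,
    sigma_log_flux: float = 0.5,
    pause_sites: int = 0,
    pause_fold: float = 10.0,
    seed: int = 0,
) -> SimTruth:
    """Draw ground-truth dwell times, fluxes, abundances and pause sites.

    Global codon dwells are log-normal (median 1, log-sd
    ``sigma_log_global``); per-gene dwells vary log-normally around the
    global value with log-sd ``sigma_log_gene``; fluxes J are log-normal.
    ``pause_sites`` positions per gene (chosen in the restricted region when
    possible) get their dwell multiplied by ``pause_fold``.
    """
    rng = np.random.default_rng(seed)
    mu_global = {
        c: float(np.exp(rng.normal(0.0, sigma_log_global))) for c in SENSE_CODONS
    }
    mu_gene: dict[tuple[str, str], float] = {}
    J: dict[str, float] = {}
    M: dict[str, float] = {}
    pauses: list[tuple[str, int, float]] = []
    for g, rec in genes.items():
        J[g] = float(np.exp(rng.normal(0.0, sigma_log_flux)))
        M[g] = float(np.exp(rng.normal(0.0, 0.5)))
        for c in sorted(set(rec.codons)):
            mu_gene[(g, c)] = mu_global[c] * float(
                np.exp(rng.normal(0.0, sigma_log_gene))
            )
        if pause_sites > 0:
            L = rec.n_codons
            lo = min(100, L - 1) if L >= 100 else int(np.ceil(0.25 * L))
            ks = rng.choice(np.arange(lo, L), size=min(pause_sites, L - lo),
                            replace=False)
            for k in np.sort(ks):
                pauses.append((g, int(k), pause_fold))
    return SimTruth(genes, mu_global, mu_gene, J, M, pauses, seed)


def simulate_footprints(
    truth: SimTruth,
    depth: float = 20.0,
    mrna_depth: float = 10.0,
    seed: int | None = None,
) -> dict[str, FootprintProfile]:
    """Poisson-sample footprint profiles from the stated truth.

    d_mk ~ Poisson(depth * J_m * mu_m^c(m,k) * pause_fold(m,k)); mRNA counts
    are position-uniform Poisson with mean ``mrna_depth * M_m``.
    """
    if depth < 0:
        raise ValueError("depth must be non-negative")
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    fold: dict[tuple[str, int], float] = {
        (g, k): f for g, k, f in truth.pause_sites
    }
    profiles: dict[str, FootprintProfile] = {}
    for g, rec in truth.genes.items():
        cods = rec.codons
        lam = np.array(
            [
                depth * truth.J[g] * truth.mu_gene[(g, c)]
                * fold.get((g, k), 1.0)
                for k, c in enumerate(cods)
            ]
        )
        counts = rng.poisson(lam)
        mcounts = rng.poisson(mrna_depth * truth.mrna_abundance[g], size=len(cods))
        profiles[g] = FootprintProfile(g, counts, mcounts,
                                       truth.mrna_abundance[g])
    return profiles


def planted_motif(
    preferred: str = "AAAAAATCC",
    strength: float = 2.0,
    seed: int = 0,
) -> KozakWeights:
    """A planted motif with one preferred base per non-AUG position.

    Weights are zero-mean per position (preferred base -0.75 * strength,
    the other three +0.25 * strength) so that x . g is centred at zero over
    random contexts and the sigmoid feature actually varies between genes
    — an all-or-nothing motif saturates the sigmoid and plants an
    unidentifiable, nearly constant effect.
    """
    if len(preferred) != 9:
        raise ValueError("need one preferred base per non-AUG position")
    x = np.full(36, 0.25 * strength)
    for j, b in enumerate(preferred):
        x[4 * j + BASES.index(b)] = -0.75 * strength
    return KozakWeights(x)


def simulate_te_dataset(
    n_genes: int,
    motif: KozakWeights | None = None,
    effect_size: float = 1.0,
    noise_sd: float = 0.3,
    n_features: int = 4,
    seed: int = 0,
) -> tuple[list[str], np.ndarray, np.ndarray, dict]:
    """Simulate (contexts, features, te) with a planted Kozak effect.

    log TE = baseline + effect_size * f_kozak(context; motif)
             + linear effects of ``n_features`` standard-normal gene
             features + Gaussian noise.  Returns contexts, the feature
             matrix, strictly-positive TE values, and the truth dict
             (planted motif, feature weights).
    """
    if effect_size < 0:
        raise ValueError("effect size must be >= 0")
    rng = np.random.default_rng(seed)
    motif = motif or planted_motif()
    contexts = []
    for _ in range(n_genes):
        up = "".join(rng.choice(list(BASES), size=6))
        down = "".join(rng.choice(list(BASES), size=3))
        contexts.append(up + "ATG" + down)
    X = rng.normal(size=(n_genes, n_features))
    w_true = rng.normal(0.0, 0.5, size=n_features)
    f_k = np.array([kozak_feature(c, motif) for c in contexts])
    log_te = 1.0 + effect_size * f_k + X @ w_true + rng.normal(0, noise_sd, n_genes)
    te = np.exp(log_te)
    return contexts, X, te, {"motif": motif, "w": w_true,
                             "effect_size": effect_size}


def simulate_dms_counts(
    sequence: str,
    accessibility: np.ndarray,
    depth: float = 100.0,
    background: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Poisson DMS-like counts: A/C positions get mean depth *
    accessibility; G/T positions get ``background`` * depth."""
    acc = np.asarray(accessibility, dtype=float)
    seq = sequence.upper().replace("U", "T")
    if acc.size != len(seq):
        raise ValueError("accessibility track must match sequence length")
    if np.any((acc < 0) | (acc > 1)):
        raise ValueError("accessibility must be in [0, 1]")
    rng = np.random.default_rng(seed)
    is_ac = np.array([b in "AC" for b in seq])
    lam = np.where(is_ac, depth * acc, background * depth)
    return rng.poisson(lam)
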