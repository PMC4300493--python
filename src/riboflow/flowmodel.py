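"""Flow-conservation dwell-time model for ribosome profiling counts.

At steady state, with no ribosome drop-off, the flow of ribosomes through
every codon of a message equals its protein synthesis rate J_m, and the
observed footprint count d_mk (a proxy for occupancy) is proportional to
J_m * mu_mk, where mu_mk is the ribosome dwell time at that codon.  The
model shares one dwell mu_m^c across all copies of codon c on message m and
softly ties it, in log space, to a global codon dwell mu^c through a
weighted penalty; the weight w_m^c is the share of codon c's genome-wide
(restricted-region) occurrences that fall on gene m, so genes with more
copies of c get a larger vote.

With flow fixed (J_m = D_m, the mean raw count per codon), the default
squared-error-in-log-space objective

    sum_m sum_{k in K'_m} (log d'_mk - log mu_m^{c(m,k)})^2
      + C * sum_c sum_m w_m^c (log mu_m^c - log mu^c)^2

separates across codons, and each codon's subproblem is an exactly solvable
ridge-type system: writing beta_m = log mu_m^c, y = log d',

    beta_m = (sum_k y_mk + C w_m^c betabar) / (n_m^c + C w_m^c),
    betabar = sum_m w_m^c beta_m   (sum_m w_m^c = 1),

which this module solves in closed form.  Coordinate descent over codons
therefore converges in a single sweep; the sweep loop and objective trace
are retained for generality (the Poisson quasi-likelihood alternative,
selectable via config, needs iterative solves).
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping
from typing import Literal

import numpy as np
from scipy import optimize

from riboflow.ioformats import FootprintProfile, GeneRecord

__all__ = [
    "FitConfig", "TransformedCounts", "ModelFit",
    "restricted_positions", "transform_counts", "baseline_dwells",
    "objective_value", "solve_codon_subproblem", "fit_model",
    "compute_flows", "codon_rates",
]


@dataclasses.dataclass(frozen=True)
class LBFGSOptions:
    max_iter: int = 5000
    grad_tol: float = 1e-5
    fun_tol: float = 1e3


@dataclasses.dataclass(frozen=True)
class DescentOptions:
    weight_tol: float = 5e-5
    fun_tol: float = 1e-5
    max_sweeps: int = 50


@dataclasses.dataclass(frozen=True)
class FitConfig:
    """Settings for :func:`fit_model`.

    C is the soft-constraint weight tying per-gene dwells to global codon
    dwells (default 100, chosen so the penalty is not greatly outweighed by
    the data term).  ``mean_dwell`` is the log-space centring target for the
    initial dwells; by default it is recomputed from the data as the mean of
    the transformed counts d' (the analogue of the published per-sample
    value 7.2).
    """

    C: float = 100.0
    mode: Literal["per_gene_codon", "per_position", "global_only"] = "per_gene_codon"
    loss: Literal["log_gaussian", "poisson"] = "log_gaussian"
    seed: int = 0
    lbfgs: LBFGSOptions = dataclasses.field(default_factory=LBFGSOptions)
    descent: DescentOptions = dataclasses.field(default_factory=DescentOptions)
    mean_dwell: float | None = None
    iterate: int = 1  # passes of (fit dwells, recompute J); 1 matches the method

    def __post_init__(self) -> None:
        if self.C < 0:
            raise ValueError("C must be >= 0")


@dataclasses.dataclass
class TransformedCounts:
    """Pseudo-counted, flow-normalized, globally rescaled counts d'.

    d'_mk = global_scale * (d_mk + 1) / J_fixed(m), with global_scale chosen
    so the smallest included value is exactly 1.  ``gene_mean`` holds the raw
    per-codon mean D_m; ``restricted`` the training positions K'_m; and
    ``codons`` the codon identity track used to pool positions.
    """

    dprime: dict[str, np.ndarray]
    global_scale: float
    gene_mean: dict[str, float]
    restricted: dict[str, range]
    codons: dict[str, np.ndarray] | None = None

    @property
    def mean_dprime(self) -> float:
        total = sum(float(v.sum()) for v in self.dprime.values())
        n = sum(v.size for v in self.dprime.values())
        return total / n


@dataclasses.dataclass
class ModelFit:
    """Fitted dwells and flows.

    mu_gene maps (gene, codon) -> mu_m^c (defined only for codons occurring
    in the gene's restricted region); mu_global maps codon -> mu^c; J maps
    gene -> synthesis rate on the transformed-count scale; weights holds
    w_m^c.  mu_pos is populated only in per-position mode.
    """

    mu_gene: dict[tuple[str, str], float]
    mu_global: dict[str, float]
    J: dict[str, float]
    weights: dict[tuple[str, str], float]
    objective_trace: list[float]
    config: FitConfig
    mu_pos: dict[str, np.ndarray] | None = None
    n_sweeps: int = 0


def restricted_positions(n_codons: int) -> range:
    """Training positions for a gene of ``n_codons`` sense codons.

    The first 100 codons are ignored (the first 25%, rounded up, for genes
    shorter than 100 codons) because flow conservation may not hold in the
    early elongation region.  The terminal stop codon is never included
    because profiles cover sense codons only.  A gene of exactly 100 codons
    yields an empty range and is unusable for training.
    """
    if n_codons < 1:
        raise ValueError("gene must have at least one codon")
    start = 100 if n_codons >= 100 else math.ceil(0.25 * n_codons)
    return range(start, n_codons)


def transform_counts(
    profiles: Mapping[str, FootprintProfile],
    genes: Mapping[str, GeneRecord] | None = None,
    J_fixed: Mapping[str, float] | None = None,
) -> TransformedCounts:
    """Build d' from raw counts: add pseudo-count 1, divide by the fixed
    flow, and rescale all genes by one global factor so the minimum is 1."""
    if not profiles:
        raise ValueError("no profiles supplied")
    gene_mean = {g: p.mean_count for g, p in profiles.items()}
    if J_fixed is None:
        J_fixed = gene_mean
    raw: dict[str, np.ndarray] = {}
    current_min = np.inf
    for g, prof in profiles.items():
        j = float(J_fixed[g])
        if not (j > 0) or not np.isfinite(j):
            raise ValueError(f"gene {g}: fixed flow must be finite and positive")
        v = (prof.counts.astype(np.float64) + 1.0) / j
        if not np.all(np.isfinite(v)):
            raise ValueError(f"gene {g}: non-finite transformed count")
        raw[g] = v
        current_min = min(current_min, float(v.min()))
    scale = 1.0 / current_min
    dprime = {g: v * scale for g, v in raw.items()}
    restricted = {g: restricted_positions(p.length) for g, p in profiles.items()}
    codons = None
    if genes is not None:
        codons = {
            g: np.asarray(genes[g].codons, dtype=object)
            for g in profiles if g in genes
        }
        for g in codons:
            if codons[g].size != profiles[g].length:
                raise ValueError(f"gene {g}: codon track and profile length differ")
    return TransformedCounts(dprime, scale, gene_mean, restricted, codons)


def baseline_dwells(
    profiles: Mapping[str, FootprintProfile],
    genes: Mapping[str, GeneRecord],
) -> tuple[dict[str, float], dict[str, float]]:
    """Baseline per-codon dwell: mean of pseudo-counted counts normalized by
    the per-gene average D_m, over restricted positions only.  Rate is the
    reciprocal of dwell.  Codons absent from every restricted region are
    missing from the output."""
    sums: dict[str, float] = {}
    ns: dict[str, int] = {}
    for g, prof in profiles.items():
        D = prof.mean_count
        if D <= 0:
            continue
        cods = genes[g].codons
        r = restricted_positions(prof.length)
        vals = (prof.counts[r.start:r.stop] + 1.0) / D
        for c, v in zip(cods[r.start:r.stop], vals):
            sums[c] = sums.get(c, 0.0) + float(v)
            ns[c] = ns.get(c, 0) + 1
    dwell = {c: sums[c] / ns[c] for c in sorted(sums)}
    rate = {c: 1.0 / d for c, d in dwell.items()}
    return dwell, rate


# ---------------------------------------------------------------------------
# Sufficient statistics and subproblem solvers


def _codon_stats(tc: TransformedCounts):
    """Per-codon training statistics over restricted positions.

    Returns {codon: (gene_ids, n_m, sum_log, sum_dprime, sum_log_sq)} with
    genes in insertion order of tc.dprime, and the penalty weights w_m^c
    (occurrence share of codon c on gene m within restricted regions).
    """
    if tc.codons is None:
        raise ValueError("TransformedCounts lacks codon identities; pass genes")
    acc: dict[str, dict[str, list[float]]] = {}
    for g, dp in tc.dprime.items():
        if g not in tc.codons:
            continue
        r = tc.restricted[g]
        if len(r) == 0:
            continue
        cods = tc.codons[g][r.start:r.stop]
        vals = dp[r.start:r.stop]
        logs = np.log(vals)
        for c in np.unique(cods):
            m = cods == c
            st = acc.setdefault(str(c), {})
            st[g] = [
                float(m.sum()), float(logs[m].sum()),
                float(vals[m].sum()), float((logs[m] ** 2).sum()),
            ]
    stats = {}
    for c in sorted(acc):
        gids = list(acc[c].keys())
        arr = np.array([acc[c][g] for g in gids], dtype=np.float64)
        n, slog, sdp, slog2 = arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]
        stats[c] = (gids, n, slog, sdp, slog2)
    return stats


def _solve_gaussian(n, slog, w, C):
    """Exact minimizer of sum_m [slog2 - 2 beta_m slog + n beta_m^2] +
    C sum_m w_m (beta_m - betabar)^2 over (beta, betabar)."""
    denom = n + C * w
    a = C * w / denom
    b = slog / denom
    ws = w / w.sum()
    sa = float(np.sum(ws * a))
    if sa >= 1.0:  # only possible when all n_m == 0, which cannot happen
        raise ZeroDivisionError("degenerate subproblem")
    betabar = float(np.sum(ws * b) / (1.0 - sa))
    beta = b + a * betabar
    return beta, betabar


def _solve_poisson(n, slog, sdp, w, C, beta0, bbar0, lbfgs: LBFGSOptions):
    """Numeric minimizer of sum_m [n_m mu_m - sdp_m log mu_m] +
    C sum_m w_m (log mu_m - betabar)^2 in log-parameter space."""

    def fg(x):
        beta, bbar = x[:-1], x[-1]
        mu = np.exp(beta)
        dev = beta - bbar
        f = float(np.sum(n * mu - sdp * beta) + C * np.sum(w * dev**2))
        gb = n * mu - sdp + 2.0 * C * w * dev
        gbar = -2.0 * C * float(np.sum(w * dev))
        return f, np.append(gb, gbar)

    x0 = np.append(beta0, bbar0)
    res = optimize.minimize(
        fg, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": lbfgs.max_iter, "gtol": lbfgs.grad_tol,
                 "ftol": 1e-12},
    )
    return res.x[:-1], float(res.x[-1])


def solve_codon_subproblem(
    codon: str,
    tc: TransformedCounts,
    C: float = 100.0,
    weights: Mapping[str, float] | None = None,
    loss: str = "log_gaussian",
    lbfgs: LBFGSOptions | None = None,
) -> tuple[dict[str, float], float]:
    """Minimize the objective over codon ``codon``'s parameters only.

    Returns ({gene: mu_m^c}, mu^c).  Under the default log-Gaussian loss the
    exact closed form is used; under the Poisson loss a quasi-Newton solve.
    ``weights`` overrides the occurrence-share penalty weights w_m^c.
    """
    stats = _codon_stats(tc)
    if codon not in stats:
        raise ValueError(f"codon {codon} absent from every restricted region")
    gids, n, slog, sdp, _ = stats[codon]
    if weights is None:
        w = n / n.sum()
    else:
        w = np.array([weights[g] for g in gids], dtype=np.float64)
    if loss == "log_gaussian":
        beta, bbar = _solve_gaussian(n, slog, w, C)
    elif loss == "poisson":
        beta0 = np.log(np.maximum(sdp / n, 1e-12))
        beta, bbar = _solve_poisson(
            n, slog, sdp, w, C, beta0, float(np.mean(beta0)),
            lbfgs or LBFGSOptions(),
        )
    else:
        raise ValueError(f"unknown loss {loss!r}")
    return dict(zip(gids, np.exp(beta))), float(np.exp(bbar))


def objective_value(fit: ModelFit, tc: TransformedCounts) -> float:
    """Evaluate the full objective for a parameter set.

    Data term over restricted positions plus C times the weighted log-space
    penalty tying mu_m^c to mu^c.
    """
    loss = fit.config.loss
    data = 0.0
    for g, dp in tc.dprime.items():
        if tc.codons is None or g not in tc.codons:
            continue
        r = tc.restricted[g]
        if len(r) == 0:
            continue
        cods = tc.codons[g][r.start:r.stop]
        vals = dp[r.start:r.stop]
        if fit.mu_pos is not None:
            mu = fit.mu_pos[g][r.start:r.stop]
        else:
            mu = np.array(
                [fit.mu_gene.get((g, c), fit.mu_global.get(c)) for c in cods],
                dtype=np.float64,
            )
        if np.any(~np.isfinite(mu)) or np.any(mu <= 0):
            raise ValueError(f"gene {g}: non-positive dwell in objective")
        if loss == "log_gaussian":
            data += float(np.sum((np.log(vals) - np.log(mu)) ** 2))
        else:
            data += float(np.sum(mu - vals * np.log(mu)))
    pen = 0.0
    if fit.mu_pos is None:
        for (g, c), mu_mc in fit.mu_gene.items():
            w = fit.weights.get((g, c), 0.0)
            pen += w * (math.log(mu_mc) - math.log(fit.mu_global[c])) ** 2
    else:
        for g, mu_arr in fit.mu_pos.items():
            r = tc.restricted[g]
            if len(r) == 0:
                continue
            cods = tc.codons[g][r.start:r.stop]
            mug = np.array([fit.mu_global[c] for c in cods])
            wts = np.array([fit.weights[(g, c)] for c in cods])
            pen += float(
                np.sum(wts * (np.log(mu_arr[r.start:r.stop]) - np.log(mug)) ** 2)
            )
    return data + fit.config.C * pen


# ---------------------------------------------------------------------------
# Full fit


def fit_model(
    genes: Mapping[str, GeneRecord],
    profiles: Mapping[str, FootprintProfile],
    config: FitConfig | None = None,
) -> ModelFit:
    """Fit dwell times and synthesis rates to footprint profiles.

    The flow is fixed to the mean raw count D_m, counts are transformed to
    d', dwells are initialized from the baseline estimator centred in log
    space on the data mean (plus a small seeded perturbation), coordinate
    descent over codons runs to convergence, and flows are recomputed from
    the fitted dwells.  Deterministic given the config seed.
    """
    config = config or FitConfig()
    usable = {
        g: p for g, p in profiles.items()
        if len(restricted_positions(p.length)) > 0 and p.mean_count > 0
    }
    if not usable:
        raise ValueError("no gene has a nonempty restricted region")
    tc = transform_counts(profiles, genes=genes)
    tc_train = TransformedCounts(
        {g: tc.dprime[g] for g in usable}, tc.global_scale,
        {g: tc.gene_mean[g] for g in usable},
        {g: tc.restricted[g] for g in usable},
        {g: tc.codons[g] for g in usable},
    )
    if config.mode == "per_position":
        fit = _fit_per_position(tc_train, config)
    else:
        fit = _fit_per_gene_codon(tc_train, config)
    fit.J = compute_flows(tc, fit)
    return fit


def _initial_log_dwells(tc: TransformedCounts, config: FitConfig, codons):
    """Baseline dwells recentred so mean log dwell is log(mean d'), the
    per-sample analogue of the published constant 7.2."""
    target = config.mean_dwell if config.mean_dwell is not None else tc.mean_dprime
    stats = _codon_stats(tc)
    base = {c: stats[c][2].sum() / stats[c][1].sum() for c in codons}  # mean log d'
    shift = math.log(target) - float(np.mean([base[c] for c in codons]))
    return {c: base[c] + shift for c in codons}


def _fit_per_gene_codon(tc: TransformedCounts, config: FitConfig) -> ModelFit:
    stats = _codon_stats(tc)
    codons = sorted(stats)  # fixed lexicographic coordinate order
    rng = np.random.default_rng(config.seed)
    init = _initial_log_dwells(tc, config, codons)

    weights: dict[tuple[str, str], float] = {}
    beta: dict[str, np.ndarray] = {}
    bbar: dict[str, float] = {}
    wvec: dict[str, np.ndarray] = {}
    for c in codons:
        gids, n, slog, sdp, _ = stats[c]
        w = n / n.sum()
        wvec[c] = w
        for g, wm in zip(gids, w):
            weights[(g, c)] = float(wm)
        beta[c] = init[c] + rng.uniform(-0.01, 0.01, size=len(gids))
        bbar[c] = init[c] + float(rng.uniform(-0.01, 0.01))

    global_only = config.mode == "global_only"

    def as_fit() -> ModelFit:
        mu_gene: dict[tuple[str, str], float] = {}
        mu_global: dict[str, float] = {}
        for c in codons:
            gids = stats[c][0]
            mu_global[c] = float(np.exp(bbar[c]))
            if not global_only:
                for g, b in zip(gids, beta[c]):
                    mu_gene[(g, c)] = float(np.exp(b))
        return ModelFit(
            mu_gene=mu_gene, mu_global=mu_global, J={},
            weights={} if global_only else weights,
            objective_trace=trace, config=config,
        )

    trace: list[float] = []
    trace.append(objective_value(as_fit(), tc))
    prev_obj = trace[0]
    n_sweeps = 0
    for _sweep in range(config.descent.max_sweeps):
        max_delta = 0.0
        for c in codons:
            gids, n, slog, sdp, _ = stats[c]
            if global_only:
                if config.loss == "log_gaussian":
                    new_bbar = float(slog.sum() / n.sum())
                else:
                    # stationary point of sum n mu - sdp log mu (single mu)
                    new_bbar = float(np.log(sdp.sum() / n.sum()))
                max_delta = max(max_delta, abs(new_bbar - bbar[c]))
                bbar[c] = new_bbar
                continue
            if config.loss == "log_gaussian":
                nb, nbb = _solve_gaussian(n, slog, wvec[c], config.C)
            else:
                nb, nbb = _solve_poisson(
                    n, slog, sdp, wvec[c], config.C, beta[c], bbar[c], config.lbfgs
                )
            max_delta = max(
                max_delta,
                float(np.max(np.abs(nb - beta[c]))),
                abs(nbb - bbar[c]),
            )
            beta[c], bbar[c] = nb, nbb
        n_sweeps += 1
        obj = objective_value(as_fit(), tc)
        trace.append(obj)
        if max_delta < config.descent.weight_tol:
            break
        if abs(prev_obj - obj) < config.descent.fun_tol:
            break
        prev_obj = obj
    fit = as_fit()
    fit.n_sweeps = n_sweeps
    return fit


def _fit_per_position(tc: TransformedCounts, config: FitConfig) -> ModelFit:
    """Model variant with a separate dwell per position, each softly tied to
    its codon's global dwell with weight 1/n_c."""
    stats = _codon_stats(tc)
    codons = sorted(stats)
    rng = np.random.default_rng(config.seed)
    target = config.mean_dwell if config.mean_dwell is not None else tc.mean_dprime

    # per-position initialization: d_mk / D_m with zeros replaced by the mean
    # of non-zero raw counts, recentred in log space
    mu_pos: dict[str, np.ndarray] = {}
    logs_all = []
    for g, dp in tc.dprime.items():
        raw = dp / tc.global_scale * tc.gene_mean[g] - 1.0  # back to raw counts
        raw = np.round(np.maximum(raw, 0.0))
        nz = raw[raw > 0]
        fill = float(nz.mean()) if nz.size else 1.0
        v = np.where(raw > 0, raw, fill) / tc.gene_mean[g]
        mu_pos[g] = np.log(v)
        r = tc.restricted[g]
        logs_all.append(mu_pos[g][r.start:r.stop])
    shift = math.log(target) - float(np.mean(np.concatenate(logs_all)))
    for g in mu_pos:
        mu_pos[g] = mu_pos[g] + shift + rng.uniform(-0.01, 0.01, size=mu_pos[g].size)

    init = _initial_log_dwells(tc, config, codons)
    bbar = {c: init[c] + float(rng.uniform(-0.01, 0.01)) for c in codons}

    # per-position weight: every position of codon c contributes 1/n_c
    n_c = {c: float(stats[c][1].sum()) for c in codons}
    weights: dict[tuple[str, str], float] = {}
    for g in tc.dprime:
        for c in np.unique(tc.codons[g]):
            if str(c) in n_c:
                weights[(g, str(c))] = 1.0 / n_c[str(c)]

    # group restricted positions by codon once
    index: dict[str, list[tuple[str, np.ndarray, np.ndarray]]] = {c: [] for c in codons}
    for g, dp in tc.dprime.items():
        r = tc.restricted[g]
        cods = tc.codons[g][r.start:r.stop]
        pos = np.arange(r.start, r.stop)
        for c in np.unique(cods):
            m = cods == c
            index[str(c)].append((g, pos[m], np.log(dp[pos[m]])))

    trace: list[float] = []

    def as_fit() -> ModelFit:
        return ModelFit(
            mu_gene={}, mu_global={c: float(np.exp(bbar[c])) for c in codons},
            J={}, weights=weights, objective_trace=trace, config=config,
            mu_pos={g: np.exp(v) for g, v in mu_pos.items()},
        )

    trace.append(objective_value(as_fit(), tc))
    prev_obj = trace[0]
    n_sweeps = 0
    # looser stopping tolerances for the position-level variant
    weight_tol, fun_tol = 1e-2, 1e-1
    for _sweep in range(config.descent.max_sweeps):
        max_delta = 0.0
        for c in codons:
            entries = index[c]
            w = 1.0 / n_c[c]
            ys, betas = [], []
            for g, pos, y in entries:
                ys.append(y)
                betas.append(mu_pos[g][pos])
            y = np.concatenate(ys)
            # each position is its own coordinate: n=1, weight w
            denom = 1.0 + config.C * w
            a = config.C * w / denom
            sa = a  # identical across positions
            b = y / denom
            new_bbar = float(np.mean(b) / (1.0 - sa))
            new_beta = b + a * new_bbar
            off = 0
            for g, pos, _y in entries:
                seg = new_beta[off:off + pos.size]
                max_delta = max(max_delta, float(np.max(np.abs(seg - mu_pos[g][pos]))))
                mu_pos[g][pos] = seg
                off += pos.size
            max_delta = max(max_delta, abs(new_bbar - bbar[c]))
            bbar[c] = new_bbar
        n_sweeps += 1
        obj = objective_value(as_fit(), tc)
        trace.append(obj)
        if max_delta < weight_tol or abs(prev_obj - obj) < fun_tol:
            break
        prev_obj = obj
    fit = as_fit()
    fit.n_sweeps = n_sweeps
    return fit


def compute_flows(tc: TransformedCounts, fit: ModelFit) -> dict[str, float]:
    """J_m = mean over the full gene of the dwell-corrected counts.

    The counts entering the flow are the pseudo-counted raw counts scaled by
    the single global factor — i.e. d' with the per-gene flow normalization
    undone (d'_mk * D_m) — so that J retains cross-gene flux information
    while sharing the scaled axis used by the outlier model.  Positions
    whose codon has no per-gene dwell (outside the restricted region, or
    genes excluded from training) fall back to the global mu^c.
    """
    J: dict[str, float] = {}
    for g, dp in tc.dprime.items():
        if fit.mu_pos is not None and g in fit.mu_pos:
            mu = fit.mu_pos[g]
        else:
            cods = tc.codons[g]
            mu = np.array(
                [fit.mu_gene.get((g, c), fit.mu_global.get(c, np.nan)) for c in cods],
                dtype=np.float64,
            )
            if np.any(np.isnan(mu)):
                missing = sorted({c for c in cods if c not in fit.mu_global
                                  and (g, c) not in fit.mu_gene})
                raise ValueError(f"gene {g}: no dwell for codons {missing}")
        J[g] = float(tc.gene_mean[g] * np.mean(dp / mu))
    return J


def codon_rates(fit: ModelFit) -> dict[str, float]:
    """Reciprocal global dwells normalized so the minimum rate is 1."""
    rates = {c: 1.0 / mu for c, mu in fit.mu_global.items()}
    lo = min(rates.values())
    return {c: r / lo for c, r in rates.items()}
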