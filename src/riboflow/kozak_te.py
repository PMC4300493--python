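"""Translation-efficiency regression with a learnable Kozak-context feature.

TE (log-transformed and z-scored) is modelled as a sparse linear function of
gene features plus a sigmoid feature of the 12-nt start-codon context:

    f_kozak = 1 / (1 + exp(x . g))

where g one-hot encodes the nine non-AUG positions (-6..-1, +4..+6; four
indicators each, 36 total) and x holds the learnable weights.  The objective

    sum_m (TE_m - w . f_m)^2 + lambda1 ||w||_1 + lambda2 (||w||_2^2 + ||x||_2^2)

is minimized by alternating an elastic-net solve for w given x with
quasi-Newton steps on x given w.  Hyperparameters come from a 5-fold
cross-validated grid search on the training split; test error is averaged
over repeated random splits, alongside a null model trained on permuted TE.

After fitting, the motif is canonicalized (an exact reparametrization
flipping the sign of x and the Kozak weight when needed) so that preferred
bases carry the largest x; the position weight matrix then shifts each
position's four weights so the most negative is 0 and normalizes by their
sum.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
from scipy import optimize
from sklearn.linear_model import ElasticNet

__all__ = [
    "KozakWeights", "RegressionFit", "KOZAK_POSITIONS",
    "kozak_similarity", "kozak_feature", "encode_context",
    "fit_te_regression", "evaluate_fixed_motif", "motif_to_pwm",
    "consensus_weights",
]

BASES = "ACGT"
# the 12-mer spans -6..+6 with AUG at +1..+3; the nine learnable positions
KOZAK_POSITIONS = (-6, -5, -4, -3, -2, -1, 4, 5, 6)
# indices of the nine non-AUG positions within the 12-nt context string
_CONTEXT_IDX = (0, 1, 2, 3, 4, 5, 9, 10, 11)

# Yeast Kozak consensus WAMAMAATGTCY (W={A,T}, M={A,C}, Y={C,T}) over the
# 12-mer; used to build a fixed comparison motif.
CONSENSUS = "WAMAMAATGTCY"
_IUPAC = {"A": "A", "C": "C", "G": "G", "T": "T",
          "W": "AT", "M": "AC", "Y": "CT"}


@dataclasses.dataclass(frozen=True)
class KozakWeights:
    """36 weights, four per non-AUG context position (order: position-major,
    bases A,C,G,T within each position)."""

    x: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=np.float64))
        if self.x.shape != (36,):
            raise ValueError("Kozak weight vector must have length 36")

    def per_position(self) -> np.ndarray:
        return self.x.reshape(9, 4)


@dataclasses.dataclass
class RegressionFit:
    w: np.ndarray
    feature_names: list[str]
    x: KozakWeights
    intercept: float
    lambda1: float
    lambda2: float
    cv_grid: list[dict]
    test_error: float
    null_error: float
    test_errors: list[float]
    null_errors: list[float]
    n_splits: int
    x_per_split: np.ndarray


def _check_context(context: str) -> str:
    context = context.upper().replace("U", "T")
    if len(context) != 12:
        raise ValueError("Kozak context must be 12 nt (-6..+6)")
    if context[6:9] != "ATG":
        raise ValueError("context positions +1..+3 must be the AUG start")
    return context


def encode_context(context: str) -> np.ndarray:
    """One-hot encode the nine non-AUG positions into the 36-vector g."""
    context = _check_context(context)
    g = np.zeros(36)
    for j, idx in enumerate(_CONTEXT_IDX):
        base = context[idx]
        if base not in BASES:
            raise ValueError(f"ambiguous base {base!r} in Kozak context")
        g[4 * j + BASES.index(base)] = 1.0
    return g


def kozak_feature(context: str, weights: KozakWeights) -> float:
    """Sigmoid context feature f = 1 / (1 + exp(x . g))."""
    z = float(weights.x @ encode_context(context))
    return float(1.0 / (1.0 + np.exp(z)))


def kozak_similarity(context: str, pwm: np.ndarray) -> float:
    """Kullback-Leibler divergence of the observed context from a 9x4 PWM.

    Sum over non-AUG positions of -log(pwm[pos, base]); 0 means the context
    sits entirely on probability-1 columns (a perfect match); a zero PWM
    probability at an observed base gives +inf.
    """
    context = _check_context(context)
    pwm = np.asarray(pwm, dtype=float)
    if pwm.shape != (9, 4):
        raise ValueError("PWM must be 9x4")
    score = 0.0
    for j, idx in enumerate(_CONTEXT_IDX):
        p = pwm[j, BASES.index(context[idx])]
        score += np.inf if p <= 0 else -float(np.log(p))
    return score


def motif_to_pwm(weights: KozakWeights | np.ndarray) -> np.ndarray:
    """Per position: shift the four weights so the minimum is 0 and divide
    by their sum; degenerate all-equal positions become uniform rows."""
    x = weights.x if isinstance(weights, KozakWeights) else np.asarray(weights)
    per_pos = x.reshape(9, 4).astype(float)
    pwm = np.empty_like(per_pos)
    for j in range(9):
        shifted = per_pos[j] - per_pos[j].min()
        tot = shifted.sum()
        pwm[j] = 0.25 if tot == 0 else shifted / tot
    return pwm


def consensus_weights(strong: float = 2.0, weak: float = 1.0) -> KozakWeights:
    """Weights for the fixed consensus motif WAMAMAATGTCY: allowed bases get
    ``strong`` (split ``weak`` for degenerate symbols), others 0, oriented so
    preferred bases carry the largest weight."""
    x = np.zeros(36)
    kept = CONSENSUS[:6] + CONSENSUS[9:]
    for j, sym in enumerate(kept):
        allowed = _IUPAC[sym]
        val = strong if len(allowed) == 1 else weak
        for b in allowed:
            x[4 * j + BASES.index(b)] = val
    return KozakWeights(x)


# ---------------------------------------------------------------------------
# Fitting


def _sigmoid_col(G: np.ndarray, x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(G @ x))


def _solve_w(
    X: np.ndarray, y: np.ndarray, lam1: float, lam2: float
) -> tuple[np.ndarray, float]:
    """Elastic-net solve of sum (y - w.X)^2 + lam1 ||w||_1 + lam2 ||w||_2^2
    (scikit-learn parametrization mapped accordingly); unpenalized intercept."""
    n = X.shape[0]
    alpha = lam1 / (2 * n) + lam2 / n
    l1_ratio = (lam1 / (2 * n)) / alpha if alpha > 0 else 0.0
    if alpha <= 0:
        coef, *_ = np.linalg.lstsq(
            np.column_stack([X, np.ones(n)]), y, rcond=None
        )
        return coef[:-1], float(coef[-1])
    en = ElasticNet(
        alpha=alpha, l1_ratio=l1_ratio, fit_intercept=True,
        max_iter=10_000, tol=1e-8,
    )
    en.fit(X, y)
    return en.coef_.copy(), float(en.intercept_)


def _solve_x(
    Xfix: np.ndarray, G: np.ndarray, y: np.ndarray,
    w: np.ndarray, b: float, wk: float, x0: np.ndarray, lam2: float,
    maxiter: int = 200,
) -> np.ndarray:
    """L-BFGS-B step on x for the smooth part of the objective (x enters
    through the sigmoid feature and the shrinkage term only)."""
    if wk == 0.0:
        return x0  # x unidentified while its weight is 0; leave unchanged

    def fg(x):
        f = _sigmoid_col(G, x)
        resid = y - (Xfix @ w + b + wk * f)
        obj = float(resid @ resid + lam2 * (x @ x))
        # d f / d x = -f (1 - f) G ; d obj / d x = 2 wk resid . f(1-f) G + 2 lam2 x
        grad = 2.0 * wk * ((resid * f * (1.0 - f)) @ G) + 2.0 * lam2 * x
        return obj, grad

    res = optimize.minimize(
        fg, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": maxiter, "gtol": 1e-6, "ftol": 1e-12},
    )
    return res.x


def _objective(Xfix, G, y, w, b, wk, x, lam1, lam2) -> float:
    pred = Xfix @ w + b + wk * _sigmoid_col(G, x)
    wfull = np.append(w, wk)
    return float(
        np.sum((y - pred) ** 2)
        + lam1 * np.sum(np.abs(wfull))
        + lam2 * (wfull @ wfull + x @ x)
    )


def _fit_one(
    Xfix: np.ndarray, G: np.ndarray, y: np.ndarray,
    lam1: float, lam2: float, x0: np.ndarray,
    fixed_x: np.ndarray | None = None,
    max_alt: int = 100, rel_tol: float = 1e-5,
) -> tuple[np.ndarray, float, float, np.ndarray]:
    """Alternate w-step and x-step until the relative objective change is
    below ``rel_tol``.  Returns (w_fixed_features, intercept, w_kozak, x)."""
    x = x0.copy() if fixed_x is None else fixed_x.copy()
    prev = np.inf
    w = np.zeros(Xfix.shape[1])
    b, wk = 0.0, 0.0
    for _ in range(max_alt):
        X = np.column_stack([Xfix, _sigmoid_col(G, x)])
        coef, b = _solve_w(X, y, lam1, lam2)
        w, wk = coef[:-1], float(coef[-1])
        if fixed_x is None:
            x = _solve_x(Xfix, G, y, w, b, wk, x, lam2)
        obj = _objective(Xfix, G, y, w, b, wk, x, lam1, lam2)
        if np.isfinite(prev) and abs(prev - obj) <= rel_tol * max(1.0, abs(prev)):
            prev = obj
            break
        prev = obj
    return w, b, wk, x


def _test_error(Xfix, G, y, w, b, wk, x) -> float:
    pred = Xfix @ w + b + wk * _sigmoid_col(G, x)
    return float(np.mean((y - pred) ** 2))


DEFAULT_GRID = (1e-3, 1e-2, 1e-1, 1.0, 10.0)


@dataclasses.dataclass(frozen=True)
class RegressionConfig:
    n_splits: int = 100
    test_size: int = 400          # or 20% of genes, whichever is smaller
    cv_folds: int = 5
    lambda_grid: tuple[float, ...] = DEFAULT_GRID
    seed: int = 0
    max_alt: int = 100
    # alternation cap during grid search; None = same as the final fit —
    # a shorter CV budget undertrains weakly-regularized candidates and
    # biases selection toward them
    cv_max_alt: int | None = None
    standardize: bool = True


def _prepare(
    features: Mapping[str, Sequence[float]] | np.ndarray,
    te: Mapping[str, float] | np.ndarray,
    contexts: Mapping[str, str] | Sequence[str],
    feature_names: list[str] | None,
    standardize: bool,
):
    if isinstance(te, Mapping):
        gids = sorted(te)
        y = np.array([te[g] for g in gids], dtype=float)
        Xfix = np.array([features[g] for g in gids], dtype=float)
        ctx = [contexts[g] for g in gids]
    else:
        y = np.asarray(te, dtype=float)
        Xfix = np.asarray(features, dtype=float)
        ctx = list(contexts)
    if np.any(y <= 0):
        raise ValueError("TE must be strictly positive (log transform applied)")
    y = np.log(y)
    y = (y - y.mean()) / y.std()
    if standardize:
        mu, sd = Xfix.mean(axis=0), Xfix.std(axis=0)
        sd[sd == 0] = 1.0
        Xfix = (Xfix - mu) / sd
    G = np.stack([encode_context(c) for c in ctx])
    names = feature_names or [f"f{i}" for i in range(Xfix.shape[1])]
    return Xfix, G, y, names


def _canonicalize(w, b, wk, x):
    """If the Kozak weight is positive, flip (x, wk) and fold the constant
    into the intercept: wk*sigmoid(x.g) = wk - wk*sigmoid(-x.g).  Exact
    reparametrization; afterwards preferred bases carry the largest x."""
    if wk > 0:
        return w, b + wk, -wk, -x
    return w, b, wk, x


def fit_te_regression(
    features: Mapping[str, Sequence[float]] | np.ndarray,
    te: Mapping[str, float] | np.ndarray,
    contexts: Mapping[str, str] | Sequence[str],
    config: RegressionConfig | None = None,
    feature_names: list[str] | None = None,
) -> RegressionFit:
    """Fit the TE regression with the learnable Kozak feature.

    Repeats over ``n_splits`` random train/test splits: grid-searches
    (lambda1, lambda2) by cross-validation on the training set, fits the
    alternating elastic-net / motif model with the best pair, and evaluates
    on the held-out genes.  The null error comes from refitting on permuted
    training TE.  The reported motif is the canonicalized average of the
    per-split x vectors.
    """
    config = config or RegressionConfig()
    Xfix, G, y, names = _prepare(features, te, contexts, feature_names,
                                 config.standardize)
    n = len(y)
    test_n = min(config.test_size, n // 5)
    if test_n < 1:
        raise ValueError("too few genes for a held-out test set")
    rng = np.random.default_rng(config.seed)
    # small seeded random start for the motif weights: at x = 0 the sigmoid
    # column is constant, the elastic net zeroes its weight, and the
    # alternation would never leave that saddle
    x_init = np.random.default_rng(config.seed + 10_007).normal(0.0, 0.1, 36)

    test_errors, null_errors, xs, lam_pairs = [], [], [], []
    cv_grid_records: list[dict] = []
    for split in range(config.n_splits):
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:test_n], perm[test_n:]
        Xtr, Gtr, ytr = Xfix[train_idx], G[train_idx], y[train_idx]
        Xte, Gte, yte = Xfix[test_idx], G[test_idx], y[test_idx]

        # hyperparameter grid search by k-fold CV on the training set
        folds = np.array_split(rng.permutation(len(ytr)), config.cv_folds)

        def grid_search(response, record):
            best, best_err = None, np.inf
            for lam1 in config.lambda_grid:
                for lam2 in config.lambda_grid:
                    errs = []
                    for f in folds:
                        mask = np.ones(len(response), dtype=bool)
                        mask[f] = False
                        w, b, wk, x = _fit_one(
                            Xtr[mask], Gtr[mask], response[mask], lam1, lam2,
                            x0=x_init,
                            max_alt=config.cv_max_alt or config.max_alt,
                        )
                        errs.append(
                            _test_error(Xtr[f], Gtr[f], response[f], w, b, wk, x)
                        )
                    cv_err = float(np.mean(errs))
                    if record:
                        cv_grid_records.append(
                            {"lambda1": lam1, "lambda2": lam2, "cv_error": cv_err}
                        )
                    if cv_err < best_err:
                        best, best_err = (lam1, lam2), cv_err
            return best

        lam1, lam2 = grid_search(ytr, record=(split == 0))
        lam_pairs.append((lam1, lam2))

        w, b, wk, x = _fit_one(Xtr, Gtr, ytr, lam1, lam2, x0=x_init,
                               max_alt=config.max_alt)
        test_errors.append(_test_error(Xte, Gte, yte, w, b, wk, x))
        w, b, wk, x = _canonicalize(w, b, wk, x)
        xs.append(x)

        # null model: the full pipeline, hyperparameter selection included,
        # run on training TE permuted among genes; evaluated against the
        # real held-out TE
        ynull = ytr[rng.permutation(len(ytr))]
        lam1n, lam2n = grid_search(ynull, record=False)
        wn, bn, wkn, xn = _fit_one(Xtr, Gtr, ynull, lam1n, lam2n,
                                   x0=x_init, max_alt=config.max_alt)
        null_errors.append(_test_error(Xte, Gte, yte, wn, bn, wkn, xn))

    x_avg = np.mean(np.stack(xs), axis=0)
    # final weights: refit on the full data with the modal hyperparameters
    vals, counts = np.unique(np.array(lam_pairs), axis=0, return_counts=True)
    lam1, lam2 = vals[np.argmax(counts)]
    w, b, wk, x_full = _fit_one(Xfix, G, y, lam1, lam2, x0=x_init,
                                max_alt=config.max_alt)
    w, b, wk, x_full = _canonicalize(w, b, wk, x_full)
    return RegressionFit(
        w=np.append(w, wk), feature_names=names + ["kozak"],
        x=KozakWeights(x_avg), intercept=b,
        lambda1=float(lam1), lambda2=float(lam2),
        cv_grid=cv_grid_records,
        test_error=float(np.mean(test_errors)),
        null_error=float(np.mean(null_errors)),
        test_errors=[float(e) for e in test_errors],
        null_errors=[float(e) for e in null_errors],
        n_splits=config.n_splits,
        x_per_split=np.stack(xs),
    )


def evaluate_fixed_motif(
    features: Mapping[str, Sequence[float]] | np.ndarray,
    te: Mapping[str, float] | np.ndarray,
    contexts: Mapping[str, str] | Sequence[str],
    fixed: KozakWeights,
    learned: RegressionFit,
    config: RegressionConfig | None = None,
    feature_names: list[str] | None = None,
) -> float:
    """Mean test error with the motif frozen to ``fixed``.

    The fixed weights are rescaled so each position's weight sum matches the
    learned motif's per-position sum, with both motifs taken in the PWM
    gauge (weights min-shifted to zero, the same gauge used for PWM export)
    — penalized learned motifs have near-zero raw sums, which would
    otherwise scale any fixed motif into a constant feature.  The scaled
    fixed weights are re-centred to zero mean per position so the sigmoid
    operates around its linear range.  Only w is learned, over the same
    split schedule and hyperparameters as the learned-motif fit.
    """
    config = config or RegressionConfig()
    Xfix, G, y, _ = _prepare(features, te, contexts, feature_names,
                             config.standardize)
    fixed_pp = fixed.per_position().copy()
    learned_pp = learned.x.per_position()
    for j in range(9):
        f_shift = fixed_pp[j] - fixed_pp[j].min()
        l_shift = learned_pp[j] - learned_pp[j].min()
        s_f, s_l = f_shift.sum(), l_shift.sum()
        if s_f > 0:
            f_scaled = f_shift * (s_l / s_f)
        else:
            f_scaled = f_shift
        fixed_pp[j] = f_scaled - f_scaled.mean()
    fixed_x = fixed_pp.reshape(36)

    n = len(y)
    test_n = min(config.test_size, n // 5)
    rng = np.random.default_rng(config.seed)  # same split schedule as fit
    errs = []
    for _split in range(config.n_splits):
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:test_n], perm[test_n:]
        w, b, wk, x = _fit_one(
            Xfix[train_idx], G[train_idx], y[train_idx],
            learned.lambda1, learned.lambda2,
            x0=fixed_x, fixed_x=fixed_x, max_alt=config.max_alt,
        )
        errs.append(_test_error(Xfix[test_idx], G[test_idx], y[test_idx],
                                w, b, wk, x))
        # keep the rng stream aligned with fit_te_regression, which draws a
        # fold permutation and a null permutation per split
        rng.permutation(len(train_idx))
        rng.permutation(len(train_idx))
    return float(np.mean(errs))
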