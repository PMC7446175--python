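"""MCMC convergence and adequacy diagnostics: split R-hat, effective sample
size, autocorrelation, and predictor collinearity.

All functions operate on plain arrays of draws grouped by chain, shape
(n_chains, n_draws) per coefficient or (n_chains, n_draws, n_coefficients)
for a whole fit, so they are independent of how the draws were produced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "split_rhat",
    "effective_sample_size",
    "autocorrelation",
    "collinearity_matrix",
    "DiagnosticsReport",
    "diagnostics_report",
    "RHAT_THRESHOLD",
    "ESS_THRESHOLD",
    "COLLINEARITY_THRESHOLD",
]

#: Convergence verdict thresholds: split R-hat below 1.01 and ESS above 10,000
#: (at the default 32,000 retained draws) are treated as adequate.
RHAT_THRESHOLD = 1.01
ESS_THRESHOLD = 10_000.0
#: Pairwise |Pearson r| at or above this flags collinearity.
COLLINEARITY_THRESHOLD = 0.8


def _as_chains(draws: np.ndarray) -> np.ndarray:
    x = np.asarray(draws, dtype=float)
    if x.ndim == 2:
        x = x[:, :, None]
    if x.ndim != 3:
        raise ValueError("expected draws of shape (chains, draws[, coefficients])")
    if x.shape[0] < 2:
        raise ValueError("at least 2 chains are required")
    return x


def split_rhat(draws: np.ndarray) -> np.ndarray | float:
    """Split-chain potential scale reduction factor.

    Each chain is split in half; with W the mean within-half variance and B
    the between-half variance of the 2·chains half-sequences of length n,

        R-hat = sqrt(((n-1)/n · W + B/n) / W).

    Approaches 1 at convergence. Chains whose draws are all identical (zero
    variance everywhere) return exactly 1.
    """
    x = _as_chains(draws)
    n_chains, n_draws, n_coef = x.shape
    if n_draws < 4:
        raise ValueError("need at least 4 draws per chain to split")
    half = n_draws // 2
    halves = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)  # (2c, half, k)
    means = halves.mean(axis=1)
    variances = halves.var(axis=1, ddof=1)
    W = variances.mean(axis=0)
    B = half * means.var(axis=0, ddof=1)
    out = np.ones(n_coef)
    ok = W > 0
    var_plus = (half - 1) / half * W[ok] + B[ok] / half
    out[ok] = np.sqrt(var_plus / W[ok])
    return out if np.asarray(draws).ndim == 3 else float(out[0])


def autocorrelation(chain: np.ndarray, max_lag: int) -> np.ndarray:
    """Autocorrelation of a single chain at lags 0..max_lag.

    Biased (divide by n) autocovariance normalised by lag 0; computed by FFT.
    """
    x = np.asarray(chain, dtype=float)
    if x.ndim != 1:
        raise ValueError("autocorrelation expects a single 1-D chain")
    n = x.size
    if not 0 <= max_lag < n:
        raise ValueError("require 0 <= max_lag < chain length")
    x = x - x.mean()
    size = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, size)
    acov = np.fft.irfft(f * np.conjugate(f), size)[: max_lag + 1] / n
    if acov[0] <= 0:
        out = np.zeros(max_lag + 1)
        out[0] = 1.0
        return out
    return acov / acov[0]


def _autocov_by_chain(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance per chain, all lags; x is (chains, draws)."""
    n = x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    size = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, size, axis=1)
    return np.fft.irfft(f * np.conjugate(f), size, axis=1)[:, :n] / n


def effective_sample_size(draws: np.ndarray) -> np.ndarray | float:
    """Effective sample size from chain-averaged autocorrelations.

    ESS = N_total / (1 + 2 Σ_t ρ_t), with ρ_t combining within-chain
    autocovariances and the between-chain variance, truncated by Geyer's
    initial monotone positive-pair rule. Antithetic chains can legitimately
    yield ESS above N_total. Zero-variance (degenerate) coefficients report
    ESS = N_total.
    """
    x = _as_chains(draws)
    n_chains, n_draws, n_coef = x.shape
    n_total = n_chains * n_draws
    out = np.empty(n_coef)
    for k in range(n_coef):
        xk = x[:, :, k]
        chain_var = xk.var(axis=1, ddof=1)
        W = chain_var.mean()
        if W <= 0:
            out[k] = float(n_total)
            continue
        B_over_n = xk.mean(axis=1).var(ddof=1)
        var_plus = (n_draws - 1) / n_draws * W + B_over_n
        acov = _autocov_by_chain(xk).mean(axis=0)
        rho = 1.0 - (W - acov) / var_plus
        # Geyer: sum consecutive pairs, truncate at first non-positive pair,
        # then enforce monotone non-increase.
        max_pairs = (n_draws - 1) // 2
        pair_sums = []
        for m in range(max_pairs):
            s = rho[2 * m] + rho[2 * m + 1]
            if s <= 0:
                break
            pair_sums.append(s)
        mono = np.minimum.accumulate(pair_sums) if pair_sums else np.array([1.0])
        tau = max(2.0 * float(np.sum(mono)) - 1.0, 1e-12)
        out[k] = n_total / tau
    return out if np.asarray(draws).ndim == 3 else float(out[0])


def collinearity_matrix(predictors) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Pairwise Pearson correlations of numeric predictor columns.

    Accepts a pandas DataFrame or a 2-D array. Returns (correlation matrix,
    flagged pairs with |r| >= 0.8). Zero-variance columns yield NaN rows and
    are reported as flagged with themselves to mark the degeneracy.
    """
    import pandas as pd

    if isinstance(predictors, pd.DataFrame):
        names = list(predictors.columns)
        X = predictors.to_numpy(dtype=float)
    else:
        X = np.asarray(predictors, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    if X.shape[0] < 3:
        raise ValueError("need at least 3 records for correlations")
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    flags: list[tuple[str, str]] = []
    for j, s in enumerate(sd):
        if s == 0:
            corr[j, :] = np.nan
            corr[:, j] = np.nan
            flags.append((names[j], names[j]))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if np.isfinite(corr[i, j]) and abs(corr[i, j]) >= COLLINEARITY_THRESHOLD:
                flags.append((names[i], names[j]))
    return corr, flags


@dataclass
class DiagnosticsReport:
    """Per-coefficient convergence metrics plus predictor collinearity."""

    coefficient_names: list[str]
    r_hat: list[float]
    ess: list[float]
    autocorr_lags: list[int]
    autocorr: dict[str, list[float]]
    collinearity: list[list[float]] | None = None
    collinearity_flags: list[tuple[str, str]] = field(default_factory=list)
    converged: bool = True
    ess_adequate: bool = True

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def diagnostics_report(posterior, cohort=None, lags=(1, 5, 10, 50),
                       ess_threshold: float | None = None) -> DiagnosticsReport:
    """Full diagnostics for a fit: R-hat and ESS per coefficient,
    chain-0 autocorrelation at selected lags, and (when a cohort is given)
    the predictor correlation matrix.

    ``ess_threshold`` defaults to 10,000 scaled by retained-draws/32,000 so
    that shorter runs are judged proportionately.
    """
    chains = posterior.by_chain()  # (c, n, d)
    names = list(posterior.names)
    rhat = np.atleast_1d(split_rhat(chains))
    ess = np.atleast_1d(effective_sample_size(chains))
    n_total = chains.shape[0] * chains.shape[1]
    if ess_threshold is None:
        ess_threshold = ESS_THRESHOLD * n_total / 32_000.0
    max_lag = min(max(lags), chains.shape[1] - 1)
    use_lags = [l for l in lags if l <= max_lag]
    ac = {}
    for j, name in enumerate(names):
        rho = autocorrelation(chains[0, :, j], max_lag)
        ac[name] = [float(rho[l]) for l in use_lags]
    corr = None
    flags: list[tuple[str, str]] = []
    if cohort is not None:
        from .bayes_logistic import build_design

        X, _, spec = build_design(cohort, None)
        import pandas as pd

        df = pd.DataFrame(X[:, 1:], columns=list(spec.predictor_names[1:]))
        corr_m, flags = collinearity_matrix(df)
        corr = corr_m.tolist()
    return DiagnosticsReport(
        coefficient_names=names,
        r_hat=[float(v) for v in rhat],
        ess=[float(v) for v in ess],
        autocorr_lags=use_lags,
        autocorr=ac,
        collinearity=corr,
        collinearity_flags=flags,
        converged=bool(np.all(rhat < RHAT_THRESHOLD)),
        ess_adequate=bool(np.all(ess > ess_threshold)),
    )
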