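"""Contact-map normalization and domain topology.

Depth scaling to a fixed cis total, Knight-Ruiz matrix balancing, the
directionality index (DI), Gaussian-HMM state decoding of the DI track, and
domain (TAD) assembly with run-length and posterior-confidence filters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM, GMMHMM

from .contacts import ContactMatrix

__all__ = [
    "normalize_depth",
    "kr_balance",
    "directionality_index",
    "fit_hmm",
    "call_tads",
    "differential_contact_map",
    "DIProfile",
    "TADSet",
    "KRConvergenceError",
]

logger = logging.getLogger(__name__)

STATE_LABELS = ("upstream", "none", "downstream")  # ordered by emission mean


class KRConvergenceError(RuntimeError):
    def __init__(self, residual: float, message: str = "") -> None:
        super().__init__(message or f"balancing did not converge (residual {residual:.3e})")
        self.residual = residual


def normalize_depth(matrix: ContactMatrix, target: float = 1e8) -> ContactMatrix:
    """Scale the matrix so its cis contact total equals ``target``.

    Relative structure is unchanged (every entry is multiplied by the same
    factor).
    """
    total = matrix.cis_total()
    if total <= 0:
        raise ValueError("cannot depth-normalize an empty contact matrix")
    out = matrix.copy()
    out.matrix *= target / total
    return out


def _kr_newton(A: np.ndarray, tol: float, max_mvp: int) -> np.ndarray | None:
    """Inner-outer Newton iteration for doubly stochastic balancing.

    Returns weights x with ``diag(x) A diag(x)`` having unit row sums, or
    None if the iteration stalls.  Conjugate-gradient inner solve with the
    usual eta safeguards.
    """
    n = A.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, big_delta = 0.1, 3.0
    g = 0.9
    etamax = 0.1
    eta = etamax
    stop_tol = tol * 0.5
    rt = tol**2
    v = x * (A @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rout = rho_km1
    rold = rout
    mvp = 0
    while rout > rt:
        k = 0
        y = e.copy()
        innertol = max(eta**2 * rout, rt)
        rho_km2 = rho_km1
        Z = p = w = None
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (A @ (x * p)) + v * p
            denom = p @ w
            if denom <= 0:
                return None
            alpha = rho_km1 / denom
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                ind = ap < 0
                gamma = ((delta - y[ind]) / ap[ind]).min()
                y += gamma * ap
                break
            if ynew.max() >= big_delta:
                ind = ynew > big_delta
                gamma = ((big_delta - y[ind]) / ap[ind]).min()
                y += gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
        x = x * y
        v = x * (A @ x)
        rk = 1.0 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        mvp += k + 1
        if mvp > max_mvp:
            return None
        rat = rout / rold
        rold = rout
        res_norm = math.sqrt(rout)
        eta_o = eta
        eta = g * rat
        if g * eta_o**2 > 0.1:
            eta = max(eta, g * eta_o**2)
        eta = max(min(eta, etamax), stop_tol / max(res_norm, 1e-300))
    return x


def _sinkhorn(A: np.ndarray, tol: float, max_iter: int) -> np.ndarray | None:
    """Symmetric iterative proportional fitting fallback; same fixed point."""
    x = np.ones(A.shape[0])
    for _ in range(max_iter):
        v = x * (A @ x)
        if np.abs(v - 1.0).max() < tol:
            return x
        x = x / np.sqrt(v)
    return None


def kr_balance(
    matrix: ContactMatrix,
    tolerance: float = 1e-8,
    max_iter: int = 3000,
) -> ContactMatrix:
    """Knight-Ruiz balancing: weights w with ``w_i M_ij w_j`` having equal
    (unit) row sums over unmasked bins.

    All-zero rows are masked and reported via NaN weights.  Newton
    iteration with a symmetric-IPF fallback if it stalls; raises
    :class:`KRConvergenceError` with the residual if neither converges.
    """
    M = matrix.matrix
    n = matrix.n_bins
    if n == 0 or M.sum() <= 0:
        raise ValueError("cannot balance an empty contact matrix")
    rowsum = M.sum(axis=1)
    mask = rowsum > 0
    if mask.sum() < 1:
        raise ValueError("no non-empty bins to balance")
    A = M[np.ix_(mask, mask)]

    x = _kr_newton(A, tolerance, max_mvp=max_iter)
    if x is None:
        logger.warning("KR Newton stalled; falling back to symmetric IPF")
        x = _sinkhorn(A, tolerance, max_iter=max_iter)
    if x is None:
        ones = np.ones(A.shape[0])
        resid = float(np.abs(1.0 - ones * (A @ ones)).max())
        raise KRConvergenceError(resid)

    weights = np.full(n, np.nan)
    weights[mask] = x
    balanced = np.zeros_like(M)
    balanced[np.ix_(mask, mask)] = x[:, None] * A * x[None, :]
    out = ContactMatrix(
        matrix=balanced,
        bin_size=matrix.bin_size,
        chrom=matrix.chrom,
        start=matrix.start,
        weights=weights,
    )
    return out


@dataclass
class DIProfile:
    """Per-bin directionality index.

    ``di`` is NaN for masked (zero-coverage) bins and for bins with no
    contacts inside the window; ``truncated`` flags edge bins whose window
    was clipped by the matrix boundary.
    """

    di: np.ndarray
    window: int
    upstream: np.ndarray
    downstream: np.ndarray
    truncated: np.ndarray
    bin_size: int = 1
    chrom: str = "chrS"
    start: int = 0

    def to_bedgraph(self, path) -> None:
        starts = self.start + np.arange(len(self.di)) * self.bin_size
        with open(path, "w") as fh:
            for s, v in zip(starts, self.di):
                if np.isnan(v):
                    continue
                fh.write(f"{self.chrom}\t{s}\t{s + self.bin_size}\t{v:.6g}\n")


def directionality_index(matrix: ContactMatrix, window: int) -> DIProfile:
    """Directionality index with an upstream/downstream window of ``window`` bins.

    ``A`` is the sum of contacts to the ``window`` upstream bins, ``B`` to
    the downstream bins, ``E = (A+B)/2``, and

        DI = sign(B - A) * ((A-E)^2/E + (B-E)^2/E)

    Positive DI means downstream bias (domain starts), negative upstream
    bias (domain ends).  Zero-coverage bins yield NaN.
    """
    if window < 1:
        raise ValueError("DI window must be at least one bin")
    M = matrix.matrix
    n = matrix.n_bins
    A = np.zeros(n)
    B = np.zeros(n)
    truncated = np.zeros(n, dtype=bool)
    for i in range(n):
        lo = max(0, i - window)
        hi = min(n, i + window + 1)
        truncated[i] = (i - window < 0) or (i + window + 1 > n)
        A[i] = M[i, lo:i].sum()
        B[i] = M[i, i + 1 : hi].sum()
    tot = A + B
    with np.errstate(divide="ignore", invalid="ignore"):
        E = tot / 2.0
        di = np.sign(B - A) * ((A - E) ** 2 / E + (B - E) ** 2 / E)
    di = np.where(tot > 0, di, np.nan)
    zero_cov = M.sum(axis=1) == 0
    di[zero_cov] = np.nan
    return DIProfile(
        di=di,
        window=window,
        upstream=A,
        downstream=B,
        truncated=truncated,
        bin_size=matrix.bin_size,
        chrom=matrix.chrom,
        start=matrix.start,
    )


def _interpolate_nan(x: np.ndarray) -> np.ndarray:
    out = x.copy()
    bad = np.isnan(out)
    if bad.all():
        raise ValueError("DI track has no finite values")
    if bad.any():
        idx = np.arange(len(out))
        out[bad] = np.interp(idx[bad], idx[~bad], out[~bad])
    return out


def fit_hmm(
    di: DIProfile | np.ndarray,
    n_states: int = 3,
    seed: int = 0,
    n_iter: int = 200,
    tol: float = 1e-4,
    mixture_components: int = 3,
) -> pd.DataFrame:
    """Decode DI hidden states with a Gaussian-mixture-emission HMM.

    Baum-Welch EM with deterministic scale-based initialization and sticky
    transitions; forward-backward posteriors are returned as a DataFrame
    whose columns are state labels ordered by emission mean (for three
    states: upstream, none, downstream).  Each state emits a
    ``mixture_components``-component Gaussian mixture (set 1 for a single
    Gaussian); the mixture is needed to model the heavy-tailed DI
    distribution inside biased runs, where the index decays smoothly from
    a boundary spike toward the mid-domain zero crossing.  Missing DI bins
    are linearly interpolated before fitting.  Rows sum to one.
    """
    values = di.di if isinstance(di, DIProfile) else np.asarray(di, dtype=float)
    x = _interpolate_nan(values).reshape(-1, 1)
    if mixture_components < 1:
        raise ValueError("mixture_components must be at least 1")
    if n_states == 3 and float(np.ptp(x)) == 0.0:
        # constant track: no directional information, everything unbiased
        post = np.zeros((len(x), 3))
        post[:, 1] = 1.0
        return pd.DataFrame(post, columns=list(STATE_LABELS))

    var = max(float(np.var(x)), 1e-8)
    startprob = np.full(n_states, 1.0 / n_states)
    trans = np.full((n_states, n_states), 0.1 / max(n_states - 1, 1))
    np.fill_diagonal(trans, 0.9)

    if mixture_components > 1:
        try:
            return _fit_hmm_mixture(
                x, n_states, mixture_components, n_iter, tol, seed,
                var=var, startprob=startprob, trans=trans,
            )
        except (ValueError, FloatingPointError):
            logger.warning(
                "mixture-emission EM degenerated (typically on very short "
                "tracks); falling back to single-Gaussian emissions"
            )
            mixture_components = 1

    qs = np.linspace(0.1, 0.9, n_states)
    model = GaussianHMM(
        n_components=n_states,
        covariance_type="diag",
        n_iter=n_iter,
        tol=tol,
        random_state=seed,
        init_params="",
        params="stmc",
    )
    model.startprob_ = startprob
    model.transmat_ = trans
    model.means_ = np.quantile(x, qs).reshape(-1, 1)
    model.covars_ = np.full((n_states, 1), var)
    model.fit(x)
    if not model.monitor_.converged:
        logger.warning(
            "HMM EM did not converge; log-likelihood trace: %s",
            list(model.monitor_.history),
        )
    post = model.predict_proba(x)
    return _label_posteriors(post, model.means_.ravel(), n_states)


def _fit_hmm_mixture(x, n_states, n_mix, n_iter, tol, seed, *, var, startprob, trans):
    # mixture means per state: spread over the DI scale, signed for the
    # biased states, near zero for the middle states
    scale = float(np.quantile(np.abs(x), 0.95)) or math.sqrt(var)
    spread = np.geomspace(0.2, 3.0, n_mix)
    centers = np.linspace(-1.0, 1.0, n_states)
    means = np.zeros((n_states, n_mix, 1))
    for i, c in enumerate(centers):
        if c < -1e-9:
            means[i, :, 0] = -spread * scale
        elif c > 1e-9:
            means[i, :, 0] = spread * scale
        else:
            means[i, :, 0] = np.linspace(-0.02, 0.02, n_mix) * scale
    model = GMMHMM(
        n_components=n_states,
        n_mix=n_mix,
        covariance_type="diag",
        n_iter=n_iter,
        tol=tol,
        random_state=seed,
        init_params="",
        params="stmcw",
    )
    model.startprob_ = startprob
    model.transmat_ = trans
    model.means_ = means
    model.covars_ = np.full((n_states, n_mix, 1), var)
    model.weights_ = np.full((n_states, n_mix), 1.0 / n_mix)
    with np.errstate(invalid="raise"):
        model.fit(x)
    if np.any(~np.isfinite(model.startprob_)) or np.any(~np.isfinite(model.means_)):
        raise ValueError("mixture EM produced non-finite parameters")
    if not model.monitor_.converged:
        logger.warning(
            "HMM EM did not converge; log-likelihood trace: %s",
            list(model.monitor_.history),
        )
    post = model.predict_proba(x)
    if np.any(~np.isfinite(post)):
        raise ValueError("mixture EM produced non-finite posteriors")
    state_means = np.einsum("sm,sm->s", model.weights_, model.means_[..., 0])
    return _label_posteriors(post, state_means, n_states)


def _label_posteriors(post: np.ndarray, state_means: np.ndarray, n_states: int) -> pd.DataFrame:
    order = np.argsort(state_means)
    post = post[:, order]
    if n_states == 3:
        labels = list(STATE_LABELS)
    else:
        labels = [f"state{i}" for i in range(n_states)]
    return pd.DataFrame(post, columns=labels)


@dataclass
class TADSet:
    """Called domains with provenance.

    ``regions`` lists every run of consecutive identical MAP states with
    its retention flag; ``domains`` are half-open bin-index intervals; each
    retained region has >= ``min_bins`` bins and median state posterior
    >= ``min_median_posterior``.
    """

    domains: list[tuple[int, int]]
    boundaries: list[int]
    regions: pd.DataFrame
    min_bins: int = 3
    min_median_posterior: float = 0.99
    posteriors: pd.DataFrame | None = field(default=None, repr=False)


def _map_states(posteriors: pd.DataFrame) -> list[str]:
    """Argmax state per bin; exact ties fall back to the unbiased state."""
    cols = list(posteriors.columns)
    vals = posteriors.to_numpy()
    out = []
    tie_label = "none" if "none" in cols else cols[len(cols) // 2]
    for row in vals:
        top = row.max()
        winners = [cols[j] for j in np.flatnonzero(row == top)]
        out.append(winners[0] if len(winners) == 1 else tie_label)
    return out


def call_tads(
    posteriors: pd.DataFrame,
    min_bins: int = 3,
    min_median_posterior: float = 0.99,
) -> TADSet:
    """Merge consecutive identical states into regions, filter, assemble TADs.

    Regions shorter than ``min_bins`` bins or with median posterior (of
    their own state) below ``min_median_posterior`` are excluded.  A TAD
    extends downstream from the start of a retained downstream-biased
    region to the end of the next retained upstream-biased region.
    """
    states = _map_states(posteriors)
    n = len(states)
    regions = []
    i = 0
    while i < n:
        j = i
        while j < n and states[j] == states[i]:
            j += 1
        block_post = posteriors.iloc[i:j][states[i]].to_numpy()
        med = float(np.median(block_post))
        n_bins = j - i
        retained = n_bins >= min_bins and med >= min_median_posterior
        reason = ""
        if n_bins < min_bins:
            reason = "too_few_bins"
        elif med < min_median_posterior:
            reason = "low_posterior"
        regions.append(
            {
                "start": i,
                "end": j,
                "state": states[i],
                "n_bins": n_bins,
                "median_posterior": med,
                "retained": retained,
                "reason": reason,
            }
        )
        i = j
    regions_df = pd.DataFrame(
        regions,
        columns=["start", "end", "state", "n_bins", "median_posterior", "retained", "reason"],
    )

    domains: list[tuple[int, int]] = []
    open_start: int | None = None
    for _, reg in regions_df[regions_df["retained"]].iterrows():
        if reg["state"] == "downstream":
            if open_start is None:
                open_start = int(reg["start"])
        elif reg["state"] == "upstream":
            if open_start is not None:
                domains.append((open_start, int(reg["end"])))
                open_start = None
    boundaries = sorted({b for d in domains for b in d})
    return TADSet(
        domains=domains,
        boundaries=boundaries,
        regions=regions_df,
        min_bins=min_bins,
        min_median_posterior=min_median_posterior,
        posteriors=posteriors,
    )


def differential_contact_map(matrix_a: ContactMatrix, matrix_b: ContactMatrix) -> np.ndarray:
    """Elementwise signed difference ``matrix_b - matrix_a`` (pass WT first,
    mutant second).  Both matrices must be identically binned and should be
    depth-normalized to the same target beforehand."""
    if matrix_a.matrix.shape != matrix_b.matrix.shape:
        raise ValueError("contact matrices have mismatched shapes")
    if matrix_a.bin_size != matrix_b.bin_size or matrix_a.start != matrix_b.start:
        raise ValueError("contact matrices are not identically binned")
    return matrix_b.matrix - matrix_a.matrix
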