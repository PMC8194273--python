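"""Multivariate autoregressive (MVAR) modelling of signal segments.

The order-p MVAR model

    x_t = sum_{k=1..p} A_k x_{t-k} + u_t,      u_t ~ N(0, C)

encodes directed lagged influence between channels: entry (i, j) of A_k
is the weight with which channel j's value k steps back drives channel i
now.  Fitting is plain multichannel least squares; a fitted model is the
input to the frequency-domain connectivity measures.

The API follows the statsmodels convention: :class:`MVARModel` is the
parameter container (usable generatively via :meth:`MVARModel.simulate`),
:func:`fit_mvar` returns an :class:`MVARResults` that additionally holds
residuals and diagnostics and prints a :meth:`~MVARResults.summary`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import Segment, ValidationError


@dataclass
class MVARModel:
    """MVAR parameter container.

    Parameters
    ----------
    coeffs : ndarray, shape (p, m, m)
        Coefficient matrices A_1..A_p.
    noise_cov : ndarray, shape (m, m)
        Innovation covariance C (symmetric, positive diagonal).
    fs : float
        Sampling rate in Hz; needed to place frequencies in physical units.
    """

    coeffs: np.ndarray
    noise_cov: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        if self.coeffs.ndim != 3 or self.coeffs.shape[1] != self.coeffs.shape[2]:
            raise ValidationError("coeffs must have shape (p, m, m)")
        m = self.coeffs.shape[1]
        if self.noise_cov.shape != (m, m):
            raise ValidationError("noise_cov shape must match channel count")
        if not np.allclose(self.noise_cov, self.noise_cov.T, atol=1e-8):
            raise ValidationError("noise_cov must be symmetric")
        if np.any(np.diag(self.noise_cov) <= 0):
            raise ValidationError("noise_cov must have strictly positive diagonal")

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def m(self) -> int:
        """Channel count."""
        return self.coeffs.shape[1]

    def companion(self) -> np.ndarray:
        """The (m·p) x (m·p) companion matrix of the lag polynomial."""
        p, m = self.order, self.m
        comp = np.zeros((m * p, m * p))
        comp[:m, :] = np.concatenate(list(self.coeffs), axis=1)
        if p > 1:
            comp[m:, :-m] = np.eye(m * (p - 1))
        return comp

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.companion()))))

    def is_stable(self, tol: float = 1e-9) -> bool:
        """Stability <=> all companion eigenvalues strictly inside the unit circle."""
        return self.spectral_radius() < 1 - tol

    def simulate(
        self, n_samples: int, seed: int | np.random.SeedSequence, burn_in: int | None = None
    ) -> np.ndarray:
        """Draw a length-``n_samples`` realisation of the process.

        Innovations are N(0, C); a burn-in (default ``10 * p * m`` samples)
        started from zeros is discarded so the output is approximately
        stationary.  Reproducible given ``seed``.
        """
        radius = self.spectral_radius()
        if radius >= 1:
            raise ValidationError(
                f"cannot simulate unstable model (spectral radius {radius:.4f} >= 1)"
            )
        p, m = self.order, self.m
        if burn_in is None:
            burn_in = 10 * p * m
        rng = np.random.default_rng(seed)
        total = n_samples + burn_in
        chol = np.linalg.cholesky(self.noise_cov)
        innovations = rng.standard_normal((total, m)) @ chol.T
        # stacked coefficients act on the flattened history [x_{t-1};..;x_{t-p}]
        stacked = np.concatenate(list(self.coeffs), axis=1)  # (m, m*p)
        x = np.zeros((total + p, m))
        for t in range(total):
            hist = x[t : t + p][::-1].ravel()  # [x_{t-1}; ...; x_{t-p}]
            x[t + p] = stacked @ hist + innovations[t]
        return x[p + burn_in :].T.copy()


def simulate_mvar(
    model: MVARModel, n_samples: int, seed: int, burn_in: int | None = None
) -> np.ndarray:
    """Functional alias for :meth:`MVARModel.simulate`."""
    return model.simulate(n_samples, seed, burn_in=burn_in)


@dataclass
class WhitenessReport:
    """Result of a multivariate portmanteau (Ljung-Box) residual test."""

    statistic: float
    dof: int
    pvalue: float
    passed: bool
    max_lag: int
    alpha: float


@dataclass
class MVARResults(MVARModel):
    """A fitted MVAR model with residuals and diagnostics attached."""

    resid: np.ndarray = field(default=None)  # (m, n - p) one-step residuals
    nobs: int = 0
    subject_id: str | None = None
    segment_index: int | None = None

    def portmanteau(self, max_lag: int = 20, alpha: float = 0.05) -> WhitenessReport:
        """Multivariate Ljung-Box whiteness test of the residuals.

        The statistic is ``n^2 * sum_{l=1..h} tr(G_l' G_0^-1 G_l G_0^-1)/(n-l)``
        on residual autocovariances G_l, chi-square with ``m^2 (h - p)``
        degrees of freedom under the white-noise null.  The pass flag is a
        diagnostic, not a hard gate on the pipeline.
        """
        if max_lag <= self.order:
            raise ValidationError(
                f"max_lag ({max_lag}) must exceed the model order ({self.order})"
            )
        u = self.resid - self.resid.mean(axis=1, keepdims=True)
        n = u.shape[1]
        if max_lag >= n:
            raise ValidationError("max_lag must be smaller than the residual length")
        g0 = (u @ u.T) / n
        g0_inv = np.linalg.inv(g0)
        q = 0.0
        for lag in range(1, max_lag + 1):
            gl = (u[:, lag:] @ u[:, :-lag].T) / n
            q += np.trace(gl.T @ g0_inv @ gl @ g0_inv) / (n - lag)
        q *= n * n
        dof = self.m**2 * (max_lag - self.order)
        pvalue = float(stats.chi2.sf(q, dof))
        return WhitenessReport(float(q), dof, pvalue, pvalue > alpha, max_lag, alpha)

    def summary(self) -> str:
        lines = [
            "MVAR fit summary",
            "----------------",
            f"channels:          {self.m}",
            f"order p:           {self.order}",
            f"observations:      {self.nobs}",
            f"sampling rate:     {self.fs:g} Hz",
            f"spectral radius:   {self.spectral_radius():.4f}",
            f"stable:            {self.is_stable()}",
            f"noise variances:   {np.array2string(np.diag(self.noise_cov), precision=4)}",
        ]
        try:
            rep = self.portmanteau()
            lines.append(
                f"portmanteau (h={rep.max_lag}): Q={rep.statistic:.2f}, "
                f"dof={rep.dof}, p={rep.pvalue:.3g} "
                f"({'white' if rep.passed else 'NOT white'})"
            )
        except ValidationError:
            pass
        return "\n".join(lines)


def fit_mvar(seg: Segment | np.ndarray, p: int, fs: float | None = None) -> MVARResults:
    """Least-squares fit of an order-``p`` MVAR model to one segment.

    Each channel's segment mean is subtracted before fitting (the
    connectivity measures assume zero-mean processes).  Coefficients
    minimise the one-step squared prediction error over t = p+1..n;
    the noise covariance is the residual covariance with denominator
    ``n - p``.

    Raises
    ------
    ValidationError
        If the segment is too short (< m*p + 1 usable time points).
    numpy.linalg.LinAlgError
        If the regressor matrix is rank deficient (e.g. a constant or
        duplicated channel).
    """
    if isinstance(seg, Segment):
        data = seg.data
        fs = seg.fs
        meta = dict(subject_id=seg.subject_id, segment_index=seg.segment_index)
    else:
        data = np.asarray(seg, dtype=float)
        if fs is None:
            raise ValidationError("fs is required when fitting a bare matrix")
        meta = dict(subject_id=None, segment_index=None)
    if p < 1:
        raise ValidationError("model order must be >= 1")
    m, n = data.shape
    if n - p < m * p + 1:
        raise ValidationError(
            f"segment too short: {n} samples leave {n - p} equations "
            f"for {m * p} regressors per channel"
        )
    x = data - data.mean(axis=1, keepdims=True)

    # regressor row t: [x_{t-1}; ...; x_{t-p}], target x_t, for t = p..n-1
    y = x[:, p:].T                                   # (n-p, m)
    regressors = np.concatenate(
        [x[:, p - k : n - k].T for k in range(1, p + 1)], axis=1
    )                                                # (n-p, m*p)
    coef, _, rank, _ = np.linalg.lstsq(regressors, y, rcond=None)
    if rank < m * p:
        raise np.linalg.LinAlgError(
            f"rank-deficient regressor matrix (rank {rank} < {m * p}); "
            "check for constant or duplicated channels"
        )
    resid = (y - regressors @ coef).T                # (m, n-p)
    noise_cov = (resid @ resid.T) / (n - p)
    coeffs = coef.T.reshape(m, p, m).transpose(1, 0, 2)
    return MVARResults(
        coeffs=coeffs, noise_cov=noise_cov, fs=float(fs),
        resid=resid, nobs=n, **meta,
    )


def portmanteau_whiteness(
    model: MVARResults, max_lag: int = 20, alpha: float = 0.05
) -> WhitenessReport:
    """Functional alias for :meth:`MVARResults.portmanteau`."""
    return model.portmanteau(max_lag=max_lag, alpha=alpha)
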