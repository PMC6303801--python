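"""Noise models and objective functions for whole-image fitting.

Pixel intensities are corrupted by multiplicative log-normal measurement
noise, ``y_m = y * eps`` with ``log eps ~ N(0, sigma^2)``. Outliers
(bright-spot artefacts from processes outside the mechanistic model) are
described by an epsilon-contamination mixture: each pixel is with
probability ``w_o`` drawn from a log-normal outlier component whose
log-location is shifted by ``mu_o`` and whose log-scale is ``sigma_o``.

Three objectives are provided:

- direct: negative log-likelihood under the pure noise model,
- filtered: the same, restricted to pixels outside a filter mask,
- integrated: negative log-likelihood under the mixture.

All computations run in log space; the mixture uses log-sum-exp. A single
shared ``sigma`` per dataset is estimated along with the mechanistic
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class NoiseModel:
    """Log-normal noise level plus optional outlier mixture component.

    sigma: log-scale standard deviation of the regular noise;
    w_o in [0, 1]: outlier probability; mu_o: outlier log-location shift
    (positive for bright artefacts, sign unconstrained); sigma_o: outlier
    log-scale. ``w_o = 0`` recovers the pure noise model.
    """

    sigma: float
    w_o: float = 0.0
    mu_o: float = 0.0
    sigma_o: float = 1.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be strictly positive")
        if not 0.0 <= self.w_o <= 1.0:
            raise ValueError("w_o must lie in [0, 1]")
        if not self.sigma_o > 0:
            raise ValueError("sigma_o must be strictly positive")

    @property
    def snr(self) -> float:
        """Closed-form signal-to-noise ratio 1/sqrt(e^{sigma^2} - 1)."""
        return 1.0 / np.sqrt(np.expm1(self.sigma**2))


def _check_positive(y_m, y) -> tuple[np.ndarray, np.ndarray]:
    y_m = np.asarray(y_m, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(y_m <= 0) or np.any(y <= 0):
        raise ValueError("intensities must be strictly positive")
    return y_m, y


def log_lognormal_pdf(y_m, y, sigma: float) -> np.ndarray:
    """log p_n(y_m | y): log-normal density with log-location log(y)."""
    if not sigma > 0:
        raise ValueError("sigma must be strictly positive")
    y_m, y = _check_positive(y_m, y)
    z = (np.log(y_m) - np.log(y)) / sigma
    return -0.5 * z**2 - np.log(sigma) - np.log(y_m) - _LOG_SQRT_2PI


def lognormal_pdf(y_m, y, sigma: float) -> np.ndarray:
    return np.exp(log_lognormal_pdf(y_m, y, sigma))


def log_outlier_pdf(y_m, y, mu_o: float, sigma_o: float) -> np.ndarray:
    """log p_o(y_m | y): log-normal with log-location log(y) + mu_o."""
    if not sigma_o > 0:
        raise ValueError("sigma_o must be strictly positive")
    y_m, y = _check_positive(y_m, y)
    z = (np.log(y_m) - (np.log(y) + mu_o)) / sigma_o
    return -0.5 * z**2 - np.log(sigma_o) - np.log(y_m) - _LOG_SQRT_2PI


def outlier_pdf(y_m, y, mu_o: float, sigma_o: float) -> np.ndarray:
    return np.exp(log_outlier_pdf(y_m, y, mu_o, sigma_o))


def log_mixture_pdf(y_m, y, noise: NoiseModel) -> np.ndarray:
    """log of the contamination mixture (1-w_o)*p_n + w_o*p_o.

    Degenerate weights return the pure component exactly; otherwise the two
    log-densities are combined with log-sum-exp.
    """
    if noise.w_o == 0.0:
        return log_lognormal_pdf(y_m, y, noise.sigma)
    if noise.w_o == 1.0:
        return log_outlier_pdf(y_m, y, noise.mu_o, noise.sigma_o)
    ln = log_lognormal_pdf(y_m, y, noise.sigma)
    lo = log_outlier_pdf(y_m, y, noise.mu_o, noise.sigma_o)
    return np.logaddexp(np.log1p(-noise.w_o) + ln, np.log(noise.w_o) + lo)


def mixture_pdf(y_m, y, noise: NoiseModel) -> np.ndarray:
    return np.exp(log_mixture_pdf(y_m, y, noise))


def _masked(data, model, mask):
    data = np.asarray(data, dtype=float)
    model = np.asarray(model, dtype=float)
    if data.shape != model.shape:
        raise ValueError("data and model shapes differ")
    if mask is None:
        return data.ravel(), model.ravel()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape:
        raise ValueError("mask shape differs from data")
    if not mask.any():
        raise ValueError("no pixels included in the objective")
    return data[mask], model[mask]


def nll_direct(data, model, sigma: float, mask=None) -> float:
    """Negative log-likelihood under the pure log-normal noise model."""
    d, m = _masked(data, model, mask)
    return float(-np.sum(log_lognormal_pdf(d, m, sigma)))


def nll_filtered(data, model, sigma: float, filter_mask, mask=None) -> float:
    """Direct negative log-likelihood over ``mask`` minus the filter set F.

    ``filter_mask`` marks pixels excluded by the (e.g. MSER) filter.
    """
    filter_mask = np.asarray(filter_mask, dtype=bool)
    data = np.asarray(data, dtype=float)
    if filter_mask.shape != data.shape:
        raise ValueError("filter mask shape differs from data")
    keep = ~filter_mask
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    if not keep.any():
        raise ValueError("filter set covers every included pixel")
    return nll_direct(data, model, sigma, mask=keep)


def nll_integrated(data, model, noise: NoiseModel, mask=None) -> float:
    """Negative log-likelihood under the outlier mixture model."""
    d, m = _masked(data, model, mask)
    return float(-np.sum(log_mixture_pdf(d, m, noise)))


def outlier_responsibility(y_m, y, noise: NoiseModel) -> np.ndarray:
    """Posterior probability that a pixel was generated by the outlier
    component, w_o*p_o / ((1-w_o)*p_n + w_o*p_o). Soft analogue of a filter
    mask: it down-weights pixels the mechanistic model cannot explain."""
    if noise.w_o == 0.0:
        y_m = np.asarray(y_m, dtype=float)
        return np.zeros_like(y_m)
    if noise.w_o == 1.0:
        y_m = np.asarray(y_m, dtype=float)
        return np.ones_like(y_m)
    lo = np.log(noise.w_o) + log_outlier_pdf(y_m, y, noise.mu_o, noise.sigma_o)
    tot = np.logaddexp(
        np.log1p(-noise.w_o) + log_lognormal_pdf(y_m, y, noise.sigma), lo
    )
    return np.exp(lo - tot)


def residuals(data, model, sigma: float, mask=None) -> np.ndarray:
    """Standardized log-residuals r = (log y_m - log y) / sigma."""
    d, m = _masked(data, model, mask)
    d, m = _check_positive(d, m)
    return (np.log(d) - np.log(m)) / sigma


def sample_noise(
    model_image: np.ndarray,
    noise: NoiseModel,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Apply multiplicative log-normal measurement noise to a model image.

    Only the regular noise component is sampled here; bright-spot outliers
    are injected structurally by the synthetic-data generator, not drawn
    from the mixture.
    """
    model_image = np.asarray(model_image, dtype=float)
    if np.any(model_image <= 0):
        raise ValueError("model image must be strictly positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.lognormal(mean=0.0, sigma=noise.sigma, size=model_image.shape)
    return model_image * eps


def empirical_snr(clean: np.ndarray, noisy: np.ndarray) -> float:
    """mean(clean) / std(noisy - clean): the empirical signal-to-noise ratio."""
    clean = np.asarray(clean, dtype=float)
    noisy = np.asarray(noisy, dtype=float)
    return float(clean.mean() / (noisy - clean).std())
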