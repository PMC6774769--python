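"""Parametric skin-colour models on two-channel chrominance planes.

Two generative models of the skin (or background) class are provided,
both operating on d = 2 chrominance observations:

* a single multivariate Gaussian (SGM), fitted in closed form by maximum
  likelihood with the biased 1/T covariance normaliser;
* a Gaussian mixture (GMM) with full-rank 2×2 component covariances,
  fitted by expectation–maximisation from a histogram-mode
  initialisation.

The module exposes both a functional surface (``fit_sgm``, ``em_e_step``,
``em_m_step``, ``fit_gmm``, ...) and a statsmodels-style object surface:
``SingleGaussianModel(X).fit()`` / ``GaussianMixtureModel(X, J).fit()``
return Results objects that evaluate densities, build per-pixel skin
probability maps and serialise to YAML.

E-step posteriors are computed in the log domain with log-sum-exp, so
outlying pixels underflow gracefully instead of dividing by zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.special import logsumexp

from .colorspace import ChrominanceImage

logger = logging.getLogger(__name__)

__all__ = [
    "SGMParams",
    "GMMParams",
    "ProbabilityMap",
    "fit_sgm",
    "mahalanobis_sq",
    "sgm_pdf",
    "gmm_pdf",
    "init_gmm",
    "em_e_step",
    "em_m_step",
    "fit_gmm",
    "probability_map",
    "threshold_map",
    "SingleGaussianModel",
    "GaussianMixtureModel",
    "SingleGaussianResults",
    "GaussianMixtureResults",
    "load_results",
]

_EIG_FLOOR = 1e-10
_REG_SCALE = 1e-6
_EMPTY_COMPONENT_FLOOR = 1e-6


def _regularise_cov(sigma: np.ndarray) -> np.ndarray:
    """Ensure symmetric positive-definiteness by adding a scaled identity.

    Applied only when the smallest eigenvalue drops below 1e-10; the ridge
    is 1e-6·trace(Σ)/d, falling back to an absolute floor for all-zero
    scatter (degenerate constant data).
    """
    sigma = 0.5 * (sigma + sigma.T)
    d = sigma.shape[0]
    if np.linalg.eigvalsh(sigma)[0] < _EIG_FLOOR:
        eps = _REG_SCALE * np.trace(sigma) / d
        if eps <= 0:
            eps = _EIG_FLOOR
        logger.warning("degenerate covariance regularised with ridge %.3e", eps)
        sigma = sigma + eps * np.eye(d)
    return sigma


def _cov_floor(X: np.ndarray) -> float:
    """Per-fit eigenvalue floor: 1e-6 · trace(global scatter)/d."""
    X = np.asarray(X, dtype=float)
    var = X.var(axis=0).sum()
    return max(_REG_SCALE * var / X.shape[1], _EIG_FLOOR)


def _floor_cov(sigma: np.ndarray, floor: float) -> np.ndarray:
    """Constrained covariance estimate: eigenvalues clipped at ``floor``.

    Clipping the eigenvalues of the weighted scatter is the maximiser of
    the Gaussian Q-function over {Σ : λ_min(Σ) ≥ floor}, so using it in
    the M-step keeps the EM likelihood non-decreasing while making
    component collapse impossible.
    """
    sigma = 0.5 * (sigma + sigma.T)
    w, V = np.linalg.eigh(sigma)
    if w[0] >= floor:
        return sigma
    logger.warning("covariance eigenvalue %.3e clipped at floor %.3e", w[0], floor)
    return (V * np.clip(w, floor, None)) @ V.T


@dataclass
class SGMParams:
    """Mean and covariance of the single-Gaussian skin model."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)

    @property
    def d(self) -> int:
        return self.mu.shape[0]


@dataclass
class GMMParams:
    """Mixture parameters {π_j, μ_j, Σ_j}, j = 1..J."""

    priors: np.ndarray
    means: np.ndarray
    covariances: np.ndarray

    def __post_init__(self) -> None:
        self.priors = np.asarray(self.priors, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        if not np.isclose(self.priors.sum(), 1.0, atol=1e-9):
            raise ValueError("mixture priors must sum to 1")
        if np.any(self.priors < 0):
            raise ValueError("mixture priors must be non-negative")

    @property
    def n_components(self) -> int:
        return len(self.priors)

    @property
    def d(self) -> int:
        return self.means.shape[1]


def _as_obs(data: np.ndarray) -> np.ndarray:
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("observations must be a (T, d) array")
    return X


def fit_sgm(data: np.ndarray) -> SGMParams:
    """Closed-form maximum-likelihood Gaussian fit.

    μ is the sample mean and Σ the biased (1/T) scatter about it; a
    near-singular Σ is ridge-regularised.
    """
    X = _as_obs(data)
    T, d = X.shape
    if T < d + 1:
        raise ValueError(f"need at least {d + 1} observations, got {T}")
    mu = X.mean(axis=0)
    centred = X - mu
    sigma = centred.T @ centred / T
    return SGMParams(mu, _regularise_cov(sigma))


def mahalanobis_sq(x: np.ndarray, params: SGMParams) -> np.ndarray:
    """Squared Mahalanobis distance (x−μ) Σ⁻¹ (x−μ)ᵀ, vectorised over rows."""
    diff = np.atleast_2d(np.asarray(x, dtype=float)) - params.mu
    solved = np.linalg.solve(params.sigma, diff.T).T
    d2 = np.einsum("ij,ij->i", diff, solved)
    return d2 if np.asarray(x).ndim > 1 else float(d2[0])


def _log_gauss(X: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    d = mu.shape[0]
    diff = X - mu
    chol = np.linalg.cholesky(sigma)
    solved = np.linalg.solve(chol, diff.T)
    d2 = np.einsum("ij,ij->j", solved, solved)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + d2)


def sgm_pdf(x: np.ndarray, params: SGMParams) -> np.ndarray:
    """Gaussian density (2π)^(−d/2) |Σ|^(−1/2) exp(−D²/2)."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    dens = np.exp(_log_gauss(X, params.mu, params.sigma))
    return dens if np.asarray(x).ndim > 1 else float(dens[0])


def _log_joint(X: np.ndarray, g: GMMParams) -> np.ndarray:
    """(T, J) matrix of log π_j + log N(x_t | μ_j, Σ_j)."""
    with np.errstate(divide="ignore"):
        logpi = np.log(g.priors)
    cols = [
        logpi[j] + _log_gauss(X, g.means[j], g.covariances[j])
        for j in range(g.n_components)
    ]
    return np.stack(cols, axis=1)


def gmm_pdf(x: np.ndarray, g: GMMParams) -> np.ndarray:
    """Mixture density Σ_j π_j N(x | μ_j, Σ_j)."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    dens = np.exp(logsumexp(_log_joint(X, g), axis=1))
    return dens if np.asarray(x).ndim > 1 else float(dens[0])


def init_gmm(
    data: np.ndarray,
    n_components: int,
    seed: int | None = 0,
    bins: int = 64,
    min_mode_separation: int = 2,
) -> GMMParams:
    """Histogram-mode initialisation of a mixture.

    A 2-D chrominance histogram (64×64 bins over the observed range) is
    computed and lightly smoothed; component means are seeded at the
    ``n_components`` strongest histogram modes (local maxima of the
    smoothed histogram, strongest occupied bins once the maxima run out)
    that are at least ``min_mode_separation`` bins apart (the separation
    requirement is relaxed if the histogram is too concentrated to
    satisfy it).  Priors start equal and every component covariance is
    the global scatter scaled by 1/J.  Deterministic for fixed inputs.
    """
    from scipy import ndimage

    X = _as_obs(data)
    T, d = X.shape
    if d != 2:
        raise ValueError("histogram initialisation requires d = 2 observations")
    if T < 3 * n_components:
        raise ValueError("too few observations for the requested component count")
    hist, xe, ye = np.histogram2d(X[:, 0], X[:, 1], bins=bins)
    occupied = np.argwhere(hist > 0)
    if len(occupied) < n_components:
        raise ValueError(
            f"only {len(occupied)} occupied histogram bins; "
            f"reduce the component count below {n_components + 1}"
        )
    smooth = ndimage.gaussian_filter(hist, sigma=max(1.0, bins / 16))
    is_peak = (smooth == ndimage.maximum_filter(smooth, size=3)) & (hist > 0)
    peaks = np.argwhere(is_peak)
    peaks = peaks[np.argsort(smooth[peaks[:, 0], peaks[:, 1]])[::-1]]
    rest = occupied[np.argsort(hist[occupied[:, 0], occupied[:, 1]])[::-1]]
    ranked = np.vstack([peaks, rest])
    for sep in range(min_mode_separation, -1, -1):
        chosen: list[np.ndarray] = []
        for cell in ranked:
            if all(np.abs(cell - c).max() >= sep for c in chosen):
                chosen.append(cell)
            if len(chosen) == n_components:
                break
        if len(chosen) == n_components:
            break
    cx = 0.5 * (xe[:-1] + xe[1:])
    cy = 0.5 * (ye[:-1] + ye[1:])
    means = np.array([[cx[i], cy[j]] for i, j in chosen])
    global_cov = _regularise_cov(np.cov(X, rowvar=False, bias=True))
    covs = np.repeat(global_cov[None] / n_components, n_components, axis=0)
    priors = np.full(n_components, 1.0 / n_components)
    return GMMParams(priors, means, covs)


def em_e_step(data: np.ndarray, g: GMMParams) -> np.ndarray:
    """Posterior component memberships h_j(x_t), rows normalised to 1."""
    X = _as_obs(data)
    log_joint = _log_joint(X, g)
    return np.exp(log_joint - logsumexp(log_joint, axis=1, keepdims=True))


def em_m_step(
    data: np.ndarray, h: np.ndarray, cov_floor: float | None = None
) -> GMMParams:
    """Closed-form M-step: responsibility-weighted means, scatter about the
    new means, and priors equal to mean responsibilities.

    Component covariances are the constrained estimates with eigenvalues
    floored at ``cov_floor`` (derived from the global data scatter when
    not given), which rules out the density singularity of collapsing
    components without breaking EM's ascent property.
    """
    X = _as_obs(data)
    h = np.asarray(h, dtype=float)
    T, J = h.shape
    floor = _cov_floor(X) if cov_floor is None else cov_floor
    weights = h.sum(axis=0)
    means = (h.T @ X) / weights[:, None]
    covs = np.empty((J, X.shape[1], X.shape[1]))
    for j in range(J):
        diff = X - means[j]
        covs[j] = _floor_cov((h[:, j] * diff.T) @ diff / weights[j], floor)
    return GMMParams(weights / T, means, covs)


def gmm_loglike(data: np.ndarray, g: GMMParams) -> float:
    """Total data log-likelihood L(X|θ)."""
    return float(logsumexp(_log_joint(_as_obs(data), g), axis=1).sum())


def fit_gmm(
    data: np.ndarray,
    n_components: int,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int | None = 0,
    init: GMMParams | None = None,
) -> tuple[GMMParams, np.ndarray]:
    """EM fit of a Gaussian mixture; returns (params, log-likelihood trace).

    Alternates posterior (E) and closed-form update (M) steps from the
    histogram initialisation, stopping when the relative change in the
    log-likelihood falls below ``tol`` or after ``max_iter`` iterations.
    A component whose total responsibility collapses below 1e-6·T is
    re-seeded at the observation the current model likes least.
    """
    X = _as_obs(data)
    T = len(X)
    g = init if init is not None else init_gmm(X, n_components, seed=seed)
    floor = _cov_floor(X)
    trace: list[float] = []
    for _ in range(max_iter):
        log_joint = _log_joint(X, g)
        per_obs = logsumexp(log_joint, axis=1)
        ll = float(per_obs.sum())
        trace.append(ll)
        h = np.exp(log_joint - per_obs[:, None])
        g = em_m_step(X, h, cov_floor=floor)
        dead = np.flatnonzero(h.sum(axis=0) < _EMPTY_COMPONENT_FLOOR * T)
        if dead.size:
            logger.warning("re-seeding %d collapsed mixture component(s)", dead.size)
            global_cov = _regularise_cov(np.cov(X, rowvar=False, bias=True))
            priors = g.priors.copy()
            means = g.means.copy()
            covs = g.covariances.copy()
            for j in dead:
                means[j] = X[int(np.argmin(per_obs))]
                covs[j] = global_cov
                priors[j] = 1.0 / T
            g = GMMParams(priors / priors.sum(), means, covs)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * abs(trace[-2]):
            break
    trace.append(gmm_loglike(X, g))
    return g, np.asarray(trace)


# ---------------------------------------------------------------------------
# probability maps


@dataclass
class ProbabilityMap:
    """Per-pixel skin score in [0, 1] for one chrominance image."""

    values: np.ndarray
    space_tag: str
    kind: str = "likelihood"  # "likelihood" (peak-normalised) or "posterior"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("probability map must be finite and non-negative")


def _density_image(img: ChrominanceImage, results) -> np.ndarray:
    flat = img.values.reshape(-1, 2)
    return results.pdf(flat).reshape(img.shape)


def probability_map(
    img: ChrominanceImage,
    skin,
    background=None,
) -> ProbabilityMap:
    """Skin probability map for a chrominance image.

    With only a skin model, returns the skin density divided by the
    model's peak density (a normalised likelihood in [0, 1], so the fixed
    decision threshold 0.55 is meaningful).  With a background model,
    returns the class posterior p_skin/(p_skin + p_bg) under equal class
    priors.
    """
    if skin.space_tag is not None and skin.space_tag != img.space_tag:
        raise ValueError(
            f"model space {skin.space_tag!r} does not match image space {img.space_tag!r}"
        )
    p_skin = _density_image(img, skin)
    if background is None:
        peak = skin.peak_density
        return ProbabilityMap(np.clip(p_skin / peak, 0.0, 1.0), img.space_tag, "likelihood")
    if background.space_tag is not None and background.space_tag != img.space_tag:
        raise ValueError("background model space does not match image space")
    p_bg = _density_image(img, background)
    total = p_skin + p_bg
    post = np.where(total > 0, p_skin / np.where(total > 0, total, 1.0), 0.5)
    return ProbabilityMap(post, img.space_tag, "posterior")


def threshold_map(pm: ProbabilityMap | np.ndarray, tau: float = 0.55) -> np.ndarray:
    """Binary skin mask: map value ≥ τ (default τ = 0.55)."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    values = pm.values if isinstance(pm, ProbabilityMap) else np.asarray(pm)
    return values >= tau


# ---------------------------------------------------------------------------
# model / results objects


class _SkinModelBase:
    """Shared constructor validation for the skin colour models."""

    def __init__(self, endog: np.ndarray, space_tag: str | None = None):
        self.endog = _as_obs(endog)
        self.space_tag = space_tag

    @property
    def nobs(self) -> int:
        return len(self.endog)


class SingleGaussianModel(_SkinModelBase):
    """Single multivariate Gaussian skin-colour model.

    Parameters
    ----------
    endog : (T, 2) array
        Chrominance observations of one class (skin or background).
    space_tag : str, optional
        Colour space the observations live in; checked against images at
        prediction time when set.
    """

    def fit(self) -> "SingleGaussianResults":
        params = fit_sgm(self.endog)
        ll = float(_log_gauss(self.endog, params.mu, params.sigma).sum())
        return SingleGaussianResults(self, params, ll)


class GaussianMixtureModel(_SkinModelBase):
    """Gaussian mixture skin-colour model fitted by EM.

    ``n_components`` defaults to 3; histogram-mode initialisation makes
    the fit deterministic for a fixed seed.
    """

    def __init__(self, endog, n_components: int = 3, space_tag: str | None = None):
        super().__init__(endog, space_tag)
        self.n_components = int(n_components)

    def fit(
        self,
        max_iter: int = 100,
        tol: float = 1e-6,
        seed: int | None = 0,
        init: GMMParams | None = None,
    ) -> "GaussianMixtureResults":
        params, trace = fit_gmm(
            self.endog, self.n_components, max_iter=max_iter, tol=tol, seed=seed, init=init
        )
        return GaussianMixtureResults(self, params, trace)


class _ResultsBase:
    """Density evaluation, probability maps and serialisation shared by
    both fitted skin models."""

    model: _SkinModelBase

    @property
    def space_tag(self) -> str | None:
        return self.model.space_tag

    def pdf(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def peak_density(self) -> float:
        raise NotImplementedError

    def probability_map(self, img: ChrominanceImage, background=None) -> ProbabilityMap:
        return probability_map(img, self, background)

    def predict_mask(
        self, img: ChrominanceImage, tau: float = 0.55, background=None
    ) -> np.ndarray:
        return threshold_map(self.probability_map(img, background), tau)

    def to_dict(self) -> dict:
        raise NotImplementedError

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def summary(self) -> str:
        raise NotImplementedError


class SingleGaussianResults(_ResultsBase):
    def __init__(self, model: SingleGaussianModel, params: SGMParams, loglike: float):
        self.model = model
        self.params = params
        self.loglike = loglike

    @property
    def mu(self) -> np.ndarray:
        return self.params.mu

    @property
    def sigma(self) -> np.ndarray:
        return self.params.sigma

    def mahalanobis_sq(self, x: np.ndarray) -> np.ndarray:
        return mahalanobis_sq(x, self.params)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return sgm_pdf(x, self.params)

    @property
    def peak_density(self) -> float:
        return float(sgm_pdf(self.params.mu, self.params))

    def to_dict(self) -> dict:
        return {
            "kind": "sgm",
            "space_tag": self.space_tag,
            "mean": self.params.mu.tolist(),
            "covariance": self.params.sigma.tolist(),
            "peak_density": self.peak_density,
        }

    def summary(self) -> str:
        lines = [
            "Single Gaussian skin-colour model",
            "=" * 40,
            f"colour space:     {self.space_tag or 'unspecified'}",
            f"observations:     {self.model.nobs}",
            f"log-likelihood:   {self.loglike:.4f}",
            f"mean:             [{self.mu[0]:.6f}, {self.mu[1]:.6f}]",
            "covariance:       "
            + np.array2string(self.sigma, precision=6, separator=", "),
        ]
        return "\n".join(lines)


class GaussianMixtureResults(_ResultsBase):
    def __init__(self, model: GaussianMixtureModel, params: GMMParams, trace: np.ndarray):
        self.model = model
        self.params = params
        self.loglike_trace = np.asarray(trace, dtype=float)
        self._peak: float | None = None

    @property
    def priors(self) -> np.ndarray:
        return self.params.priors

    @property
    def means(self) -> np.ndarray:
        return self.params.means

    @property
    def covariances(self) -> np.ndarray:
        return self.params.covariances

    @property
    def n_iter(self) -> int:
        return len(self.loglike_trace) - 1

    @property
    def loglike(self) -> float:
        return float(self.loglike_trace[-1])

    def responsibilities(self, x: np.ndarray | None = None) -> np.ndarray:
        return em_e_step(self.model.endog if x is None else x, self.params)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return gmm_pdf(x, self.params)

    @property
    def peak_density(self) -> float:
        # Peak over training data and component means; cached after first use.
        if self._peak is None:
            cand = np.vstack([self.model.endog, self.params.means])
            self._peak = float(np.max(gmm_pdf(cand, self.params)))
        return self._peak

    def to_dict(self) -> dict:
        return {
            "kind": "gmm",
            "space_tag": self.space_tag,
            "n_components": self.params.n_components,
            "priors": self.params.priors.tolist(),
            "means": self.params.means.tolist(),
            "covariances": self.params.covariances.tolist(),
            "peak_density": self.peak_density,
            "loglike_trace": self.loglike_trace.tolist(),
        }

    def summary(self) -> str:
        lines = [
            "Gaussian mixture skin-colour model (EM fit)",
            "=" * 48,
            f"colour space:     {self.space_tag or 'unspecified'}",
            f"observations:     {self.model.nobs}",
            f"components:       {self.params.n_components}",
            f"EM iterations:    {self.n_iter}",
            f"log-likelihood:   {self.loglike:.4f}",
            "",
            f"{'j':>3} {'prior':>8} {'mean':>24} {'cov eigenvalues':>24}",
        ]
        for j in range(self.params.n_components):
            eig = np.linalg.eigvalsh(self.params.covariances[j])
            lines.append(
                f"{j:>3} {self.params.priors[j]:>8.4f} "
                f"[{self.params.means[j][0]:>10.4f}, {self.params.means[j][1]:>10.4f}] "
                f"[{eig[0]:>10.3e}, {eig[1]:>10.3e}]"
            )
        return "\n".join(lines)


class _FrozenResults(_ResultsBase):
    """Results reconstructed from a serialised model document."""

    def __init__(self, doc: dict):
        self._doc = dict(doc)
        self.model = _SkinModelBase(np.zeros((2, 2)), doc.get("space_tag"))
        self.model.endog = np.zeros((0, 2))
        kind = doc["kind"]
        if kind == "sgm":
            self.params = SGMParams(doc["mean"], doc["covariance"])
            self._pdf = lambda x: sgm_pdf(x, self.params)
        elif kind == "gmm":
            self.params = GMMParams(doc["priors"], doc["means"], doc["covariances"])
            self._pdf = lambda x: gmm_pdf(x, self.params)
        else:
            raise ValueError(f"unknown model kind {kind!r}")
        self.kind = kind
        self._peak = float(doc["peak_density"])

    def pdf(self, x):
        return self._pdf(x)

    @property
    def peak_density(self) -> float:
        return self._peak

    def to_dict(self) -> dict:
        return dict(self._doc)

    def summary(self) -> str:
        return yaml.safe_dump(self._doc, sort_keys=False)


def load_results(path) -> _FrozenResults:
    """Load a serialised skin model (YAML) back into a results object."""
    with open(path) as fh:
        return _FrozenResults(yaml.safe_load(fh))
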