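"""Non-convex Bayesian phase retrieval for low-dose ptychography.

The object T is the minimizer of a maximum-a-posteriori objective built
from the Poisson negative log-likelihood of the counts,

    L(T) = sum_i [ |p_i T|^2 - y_i log |p_i T|^2 ],

plus one of two priors: a Tikhonov (gradient-smoothness) penalty
(mu0 / kappa) ||grad T||^2, or a sparse-denoiser penalty
mu1 ||T - T_sparse||^2 against a periodically refreshed denoised
reference.  Minimization uses Polak-Ribiere nonlinear conjugate gradient
with Armijo backtracking, driven by Wirtinger gradients whose unreliable
likelihood terms are discarded by a residual-size truncation rule:
measurement i is retained iff

    | y_i - |p_i T|^2 |  <=  (alpha_h / KM) ||y - I||_1 |p_i T| / ||T||_2 .

Initialization is either random (unit amplitude, Normal(0.1, 0.1)-phase)
or spectral: the phase of the dominant eigenvector of the data-masked
normal operator, obtained by power iteration with the top 20% of
intensities contributing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .denoise import denoise_complex
from .forward import ForwardOperator, ObjectField
from .geometry import ComplexField2D

__all__ = [
    "ReconConfig",
    "ReconState",
    "DenoiserState",
    "poisson_nll",
    "likelihood_gradient",
    "truncation_set",
    "truncated_likelihood_gradient",
    "tikhonov_prior",
    "tikhonov_kappa",
    "sparse_prior",
    "refresh_denoiser",
    "spectral_initialize",
    "random_initialize",
    "reconstruct",
]

logger = logging.getLogger(__name__)

# Relative floor applied inside logarithms and divisions by the model
# intensity, so that zero-intensity model pixels stay finite.
_FLOOR_REL = 1e-12


@dataclass
class ReconConfig:
    """Tuning knobs of the MAP solver.

    mu0 (Tikhonov weight) and mu1 (sparse-prior weight) default to the
    grid-searched values 1e-2 and 8e-2; the truncation parameter alpha_h
    defaults to 5 (larger keeps more measurements).  Spectral
    initialization runs ``power_iters`` power iterations with intensities
    above ``spectral_percentile`` contributing; it is only reliable at
    doses around 100 e-/A^2 and above, so ``init_mode`` defaults to
    random.
    """

    mu0: float = 1e-2
    mu1: float = 8e-2
    alpha_h: float = 5.0
    max_iters: int = 100
    rel_tol: float = 1e-7
    init_mode: str = "random"  # {"random", "spectral"}
    power_iters: int = 70
    spectral_percentile: float = 80.0
    prior: str = "none"  # {"none", "tikhonov", "sparse"}
    denoiser_id: str = "wavelet"
    refresh_interval: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        # Coerce numerics: YAML 1.1 readers hand exponent literals like
        # 1e-07 over as strings.
        for name in ("mu0", "mu1", "alpha_h", "rel_tol", "spectral_percentile"):
            object.__setattr__(self, name, float(getattr(self, name)))
        for name in ("max_iters", "power_iters", "refresh_interval", "seed"):
            object.__setattr__(self, name, int(getattr(self, name)))
        if self.mu0 < 0 or self.mu1 < 0:
            raise ValueError("prior weights must be nonnegative")
        if not (0.0 < self.spectral_percentile < 100.0):
            raise ValueError("spectral_percentile must lie in (0, 100)")
        if self.prior not in ("none", "tikhonov", "sparse"):
            raise ValueError(f"unknown prior {self.prior!r}")
        if self.init_mode not in ("random", "spectral"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")


@dataclass
class DenoiserState:
    """Denoised reference for the sparse prior."""

    t_sparse: np.ndarray
    denoiser_id: str
    refresh_interval: int = 10


@dataclass
class ReconState:
    """Result of a reconstruction run."""

    current: ObjectField
    objective_trace: list[float] = field(default_factory=list)
    truncated_fraction_trace: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False


def _floor_of(intensities: np.ndarray) -> float:
    nonzero = intensities[intensities > 0]
    if nonzero.size == 0:
        return _FLOOR_REL
    return _FLOOR_REL * float(nonzero.mean())


def poisson_nll(
    t_values: np.ndarray, y: np.ndarray, operator: ForwardOperator
) -> float:
    """Poisson negative log-likelihood sum_i [I_i - y_i log I_i] over all
    KM measurements (model intensities floored inside the log)."""
    if y.shape != (operator.n_positions, *operator.probe.field.shape):
        raise ValueError("measurement stack shape does not match the operator")
    intens = operator.intensities(t_values)
    floor = _floor_of(intens)
    # y = 0 terms contribute exactly I_i: 0 * log(...) is forced to 0.
    logs = np.where(y > 0, np.log(np.maximum(intens, floor)), 0.0)
    return float(np.sum(intens - y * logs))


def _residual_factor(
    amplitudes: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(1 - y / I) factor and the model intensities, floored."""
    intens = np.abs(amplitudes) ** 2
    floor = _floor_of(intens)
    return 1.0 - y / np.maximum(intens, floor), intens


def likelihood_gradient(
    t_values: np.ndarray, y: np.ndarray, operator: ForwardOperator
) -> np.ndarray:
    """Wirtinger gradient 2 P+[(1 - y/|PT|^2) (PT)] of the Poisson NLL.

    Scaled so that L(T + dT) ~ L(T) + Re<G, dT>: the real/imaginary parts
    of G match partial derivatives with respect to Re(T)/Im(T).
    """
    if y.shape != (operator.n_positions, *operator.probe.field.shape):
        raise ValueError("measurement stack shape does not match the operator")
    amps = operator.apply(t_values)
    factor, _ = _residual_factor(amps, y)
    return 2.0 * operator.adjoint(factor * amps)


def truncation_set(
    t_values: np.ndarray,
    y: np.ndarray,
    operator: ForwardOperator,
    alpha_h: float,
) -> np.ndarray:
    """Boolean mask over all KM measurements retained by the truncation
    rule; measurements with residuals exceeding the bound are dropped."""
    t_norm = float(np.linalg.norm(t_values))
    if t_norm == 0:
        raise ValueError("truncation rule is undefined for a zero object")
    amps = operator.apply(t_values)
    intens = np.abs(amps) ** 2
    resid = np.abs(y - intens)
    km = y.size
    bound = (alpha_h / km) * resid.sum() * np.abs(amps) / t_norm
    return resid <= bound


def truncated_likelihood_gradient(
    t_values: np.ndarray,
    y: np.ndarray,
    operator: ForwardOperator,
    alpha_h: float,
) -> tuple[np.ndarray, float]:
    """Likelihood gradient restricted to the retained measurement set.

    Returns the gradient and the retained fraction.  An empty retained
    set yields a zero gradient (logged as a warning).
    """
    amps = operator.apply(t_values)
    factor, intens = _residual_factor(amps, y)
    t_norm = float(np.linalg.norm(t_values))
    if t_norm == 0:
        raise ValueError("truncation rule is undefined for a zero object")
    resid = np.abs(y - intens)
    bound = (alpha_h / y.size) * resid.sum() * np.abs(amps) / t_norm
    mask = resid <= bound
    retained = float(mask.mean())
    if retained == 0.0:
        logger.warning("truncation discarded every measurement; zero gradient")
        return np.zeros(operator.object_shape, dtype=np.complex128), 0.0
    return 2.0 * operator.adjoint(np.where(mask, factor, 0.0) * amps), retained


# ---------------------------------------------------------------------------
# Priors

def _forward_diff(t: np.ndarray, axis: int) -> np.ndarray:
    """Forward difference with replicate boundary (last difference = 0)."""
    d = np.zeros_like(t)
    if axis == 0:
        d[:-1, :] = t[1:, :] - t[:-1, :]
    else:
        d[:, :-1] = t[:, 1:] - t[:, :-1]
    return d


def _forward_diff_adjoint(d: np.ndarray, axis: int) -> np.ndarray:
    """Adjoint of :func:`_forward_diff` under the plain inner product."""
    out = np.zeros_like(d)
    if axis == 0:
        out[:-1, :] -= d[:-1, :]
        out[1:, :] += d[:-1, :]
    else:
        out[:, :-1] -= d[:, :-1]
        out[:, 1:] += d[:, :-1]
    return out


def tikhonov_kappa(n_pix: int, n_measurements: int, i_l1: float) -> float:
    """Likelihood-matching scale kappa = 8 N_pix^2 / (N_m ||I||_1)."""
    if n_measurements <= 0 or i_l1 <= 0:
        raise ValueError("kappa needs positive N_m and ||I||_1")
    return 8.0 * n_pix**2 / (n_measurements * i_l1)


def tikhonov_prior(
    t_values: np.ndarray, mu0: float, kappa: float
) -> tuple[float, np.ndarray]:
    """Gradient-smoothness penalty (mu0/kappa) ||grad T||^2 and its
    Wirtinger gradient (discrete-Laplacian form)."""
    if not kappa > 0:
        raise ValueError("kappa must be positive")
    w = mu0 / kappa
    dx = _forward_diff(t_values, 1)
    dy = _forward_diff(t_values, 0)
    penalty = w * float(np.sum(np.abs(dx) ** 2 + np.abs(dy) ** 2))
    grad = 2.0 * w * (
        _forward_diff_adjoint(dx, 1) + _forward_diff_adjoint(dy, 0)
    )
    return penalty, grad


def sparse_prior(
    t_values: np.ndarray, denoiser_state: DenoiserState, mu1: float
) -> tuple[float, np.ndarray]:
    """Quadratic pull toward the denoised reference: mu1 ||T - T_sparse||^2
    with gradient 2 mu1 (T - T_sparse) (factor 2 keeps the gradient the
    true derivative of the stated penalty)."""
    diff = t_values - denoiser_state.t_sparse
    if diff.shape != t_values.shape:
        raise ValueError("denoiser state shape does not match the object")
    penalty = mu1 * float(np.sum(np.abs(diff) ** 2))
    return penalty, 2.0 * mu1 * diff


def refresh_denoiser(
    obj_values: np.ndarray, denoiser_id: str = "wavelet", refresh_interval: int = 10
) -> DenoiserState:
    """Recompute the sparse-prior reference by denoising the current
    iterate through domain coloring."""
    if not np.all(np.isfinite(obj_values)):
        raise ValueError("cannot denoise a non-finite field")
    return DenoiserState(
        t_sparse=denoise_complex(obj_values, denoiser_id),
        denoiser_id=denoiser_id,
        refresh_interval=refresh_interval,
    )


# ---------------------------------------------------------------------------
# Initialization

def random_initialize(
    shape: tuple[int, int], seed: int, pixel_size: float = 1.0
) -> ObjectField:
    """Unit transmission with Normal(mean 0.1, variance 0.1) phase."""
    rng = np.random.default_rng(seed)
    phase = rng.normal(0.1, np.sqrt(0.1), size=shape)
    return ObjectField(
        ComplexField2D(np.exp(1j * phase), pixel_size), passive=True
    )


def intensity_percentile_mask(y: np.ndarray, percentile: float) -> np.ndarray:
    """Indicator of the measurements above the intensity percentile;
    exactly ceil((1 - percentile/100) * KM) entries are retained."""
    km = y.size
    keep = max(1, int(np.ceil((1.0 - percentile / 100.0) * km)))
    flat = y.ravel()
    idx = np.argpartition(flat, km - keep)[km - keep :]
    mask = np.zeros(km, dtype=bool)
    mask[idx] = True
    return mask.reshape(y.shape)


def _spectral_eigenvector(
    y: np.ndarray, operator: ForwardOperator, config: ReconConfig
) -> np.ndarray:
    """Dominant eigenvector (unit norm) of the data-masked normal operator
    (Q+Q)^-1 Q+ F+ M F Q by power iteration."""
    if not np.any(y > 0):
        raise ValueError("spectral initialization needs at least one count")
    mask = intensity_percentile_mask(y, config.spectral_percentile)
    power = operator.probe_power_map()
    floor = 1e-6 * power.max()
    inv_power = 1.0 / np.maximum(power, floor)

    rng = np.random.default_rng(config.seed)
    v = rng.standard_normal(operator.object_shape) + 1j * rng.standard_normal(
        operator.object_shape
    )
    v /= np.linalg.norm(v)
    for _ in range(config.power_iters):
        v = inv_power * operator.adjoint(mask * operator.apply(v))
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError("power iteration collapsed to zero")
        v /= norm
    return v


def spectral_initialize(
    y: np.ndarray, operator: ForwardOperator, config: ReconConfig
) -> ObjectField:
    """Truncated spectral initialization.

    Power iteration on the object-space normal operator
    (Q+Q)^-1 Q+ F+ M F Q, where M keeps the measurements above the
    configured intensity percentile (default: the top 20% contribute) and
    (Q+Q)^-1 is the pointwise inverse of the summed probe intensity
    (floored to avoid division by unilluminated pixels).  Returns a
    unit-amplitude transmission carrying the dominant eigenvector's phase.
    """
    v = _spectral_eigenvector(y, operator, config)
    phase = np.angle(v)
    return ObjectField(
        ComplexField2D(np.exp(1j * phase), operator.probe.pixel_size),
        passive=True,
    )


# ---------------------------------------------------------------------------
# Conjugate-gradient MAP solver

def _real_inner(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.real(np.vdot(a, b)))


def reconstruct(
    y: np.ndarray,
    operator: ForwardOperator,
    config: ReconConfig,
    initial: ObjectField | None = None,
) -> ReconState:
    """Minimize the selected MAP objective with Polak-Ribiere nonlinear CG.

    The line search is Armijo backtracking and only accepts steps that do
    not increase the objective, restarting along steepest descent when a
    conjugate direction fails; the objective trace is therefore
    non-increasing between denoiser refreshes.  Stops after ``max_iters``
    iterations or when the relative objective change falls below
    ``rel_tol``.

    Parameters
    ----------
    y : detected counts, shape (K, m1, m2).
    operator : forward map with the known probe and scan positions.
    config : solver configuration.
    initial : optional starting object; otherwise ``config.init_mode``
        selects random or spectral initialization.
    """
    if initial is not None:
        t = initial.values.copy()
    elif config.init_mode == "spectral":
        t = spectral_initialize(y, operator, config).values.copy()
    else:
        t = random_initialize(
            operator.object_shape, config.seed, operator.probe.pixel_size
        ).values.copy()

    kappa = None
    if config.prior == "tikhonov":
        kappa = tikhonov_kappa(
            operator.probe.field.shape[0], y.size, max(float(y.sum()), 1.0)
        )
    denoiser_state = None
    if config.prior == "sparse":
        denoiser_state = refresh_denoiser(
            t, config.denoiser_id, config.refresh_interval
        )

    def objective(tv: np.ndarray) -> float:
        val = poisson_nll(tv, y, operator)
        if config.prior == "tikhonov":
            val += tikhonov_prior(tv, config.mu0, kappa)[0]
        elif config.prior == "sparse":
            val += sparse_prior(tv, denoiser_state, config.mu1)[0]
        return val

    def gradient(tv: np.ndarray) -> tuple[np.ndarray, float]:
        g, retained = truncated_likelihood_gradient(
            tv, y, operator, config.alpha_h
        )
        if config.prior == "tikhonov":
            g = g + tikhonov_prior(tv, config.mu0, kappa)[1]
        elif config.prior == "sparse":
            g = g + sparse_prior(tv, denoiser_state, config.mu1)[1]
        return g, retained

    state = ReconState(
        current=ObjectField(
            ComplexField2D(t, operator.probe.pixel_size), passive=False
        )
    )

    f = objective(t)
    if not np.isfinite(f):
        raise RuntimeError("objective is non-finite at the starting point")
    g, retained = gradient(t)
    d = -g
    step = 1.0 / max(np.linalg.norm(g), 1e-30)
    state.objective_trace.append(f)
    state.truncated_fraction_trace.append(1.0 - retained)

    for it in range(1, config.max_iters + 1):
        # Armijo backtracking; fall back to steepest descent on failure.
        accepted = False
        for direction in (d, -g):
            slope = _real_inner(g, direction)
            if slope >= 0:
                continue
            tau = step
            for _ in range(40):
                cand = t + tau * direction
                f_cand = objective(cand)
                if np.isfinite(f_cand) and f_cand <= f + 1e-4 * tau * slope:
                    accepted = True
                    break
                tau *= 0.5
            if accepted:
                break
        if not accepted:
            logger.info("line search stalled at iteration %d", it)
            break

        t = cand
        f_prev, f = f, f_cand
        step = tau * 2.0  # warm-start the next search

        refreshed = False
        if (
            config.prior == "sparse"
            and denoiser_state is not None
            and it % denoiser_state.refresh_interval == 0
        ):
            denoiser_state = refresh_denoiser(
                t, config.denoiser_id, config.refresh_interval
            )
            f = objective(t)  # reference changed; re-evaluate
            refreshed = True

        g_new, retained = gradient(t)
        beta = max(
            0.0,
            _real_inner(g_new, g_new - g) / max(_real_inner(g, g), 1e-30),
        )
        d = -g_new + beta * d
        if _real_inner(g_new, d) >= 0:  # restart on non-descent
            d = -g_new
        g = g_new

        state.objective_trace.append(f)
        state.truncated_fraction_trace.append(1.0 - retained)
        state.iterations = it
        if not np.isfinite(f):
            state.current = ObjectField(
                ComplexField2D(t, operator.probe.pixel_size), passive=False
            )
            raise RuntimeError(
                f"objective diverged at iteration {it}; trace: "
                f"{state.objective_trace[-5:]}"
            )
        # A denoiser refresh moves the objective's reference point, so the
        # change across a refresh says nothing about stationarity.
        if not refreshed and abs(f_prev - f) <= config.rel_tol * max(
            abs(f_prev), 1.0
        ):
            state.converged = True
            break

    state.current = ObjectField(
        ComplexField2D(t, operator.probe.pixel_size), passive=False
    )
    return state
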