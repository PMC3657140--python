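"""Variational-Laplace inversion of a DCM for one subject's region data.

The observation model is ``y = g(theta) + X0 beta + e`` with ``g`` the
bilinear-balloon forward model, ``X0`` low-order Legendre confounds
(projected out of data and prediction), and i.i.d. Gaussian noise with a
single precision hyperparameter shared across regions. Parameters carry
zero-mean shrinkage Gaussian priors (self-connections are parameterized as
``-0.5 exp(theta)`` so they stay negative; a few global hemodynamic
log-scales are free, the remaining balloon constants are pinned).

Fitting is expectation-maximization with local linearization: a
Gauss-Newton ascent on the free energy F with Levenberg damping for the
parameters, and a closed-form update of the noise precision. F is the
variational lower bound on log model evidence (accuracy minus complexity)
and is exact for a linear forward model, which the tests exploit. Accepted
steps never decrease F.

The generic engine (:func:`variational_laplace`) takes any prediction
callable, so reduced linear models can be inverted with the same code path
used for the full DCM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .generative_model import (
    DCMParameters,
    DCMSpec,
    HEMO_DEFAULTS,
    _input_matrix,
    _integrate_bold,
    legendre_drift_basis,
)
from .task_design import TaskDesign, build_inputs

__all__ = [
    "PriorSpec",
    "InversionResult",
    "DCMForward",
    "variational_laplace",
    "invert",
    "log_evidence",
    "b_param_name",
]

_SELF_SCALE = -0.5


@dataclass(frozen=True)
class PriorSpec:
    """Prior means and variances per parameter class.

    Variances are in Hz^2 for coupling rates and unitless for log-scale
    parameters. A zero variance pins the parameter at its prior mean.
    ``fixed_noise_precision`` pins the noise hyperparameter (used by the
    linear-Gaussian reduction); when None it is updated by EM.
    """

    intrinsic_var: float = 0.25
    modulatory_var: float = 0.25
    driving_var: float = 0.25
    self_var: float = 0.0625
    hemo_var: float = 0.0625
    hemo_free: tuple[str, ...] = ("kappa", "tau", "epsilon")
    fixed_noise_precision: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "intrinsic_var", "modulatory_var", "driving_var", "self_var", "hemo_var",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class InversionResult:
    """Posterior moments and free energy for one subject-model fit."""

    param_names: list[str]
    posterior_mean: np.ndarray
    posterior_cov: np.ndarray
    free_energy: float
    trace: list[float]
    converged: bool
    n_iter: int
    noise_precision: float
    messages: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        C = np.asarray(self.posterior_cov, dtype=float)
        if not np.allclose(C, C.T, atol=1e-8):
            raise ValueError("posterior covariance must be symmetric")
        self.posterior_cov = 0.5 * (C + C.T)

    @property
    def posterior(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.posterior_mean))

    def mean_of(self, name: str) -> float:
        return self.posterior_mean[self.param_names.index(name)]

    def sd_of(self, name: str) -> float:
        i = self.param_names.index(name)
        return float(np.sqrt(max(self.posterior_cov[i, i], 0.0)))

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        m, s = self.mean_of(name), self.sd_of(name)
        return m - z * s, m + z * s


def b_param_name(emotion: str, src: str, dst: str) -> str:
    """Parameter-vector name of a modulatory edge."""
    return f"B[{emotion}][{dst}<-{src}]"


# -- the DCM forward model as a theta -> prediction map ---------------------


class DCMForward:
    """Maps a parameter vector to a noiseless BOLD prediction.

    Precomputes the microtime input matrix and the distinct modulator
    configurations so each evaluation only assembles matrices, checks
    stability, and runs the compiled integrator.
    """

    def __init__(
        self,
        spec: DCMSpec,
        design: TaskDesign,
        priors: PriorSpec | None = None,
        inputs=None,
        microtime_bins: int | None = None,
    ) -> None:
        from dataclasses import replace as _replace

        self.spec = spec
        self.priors = priors or PriorSpec()
        if microtime_bins is not None and microtime_bins != design.microtime_bins_per_tr:
            design = _replace(design, microtime_bins_per_tr=microtime_bins)
        self.design = design
        self.inputs = build_inputs(design) if inputs is None else inputs
        n_bins = design.n_volumes * design.microtime_bins_per_tr
        self.u_all = np.ascontiguousarray(
            _input_matrix(spec, self.inputs, n_bins), dtype=float
        )
        self.n_mod = len(spec.modulator_names)
        self._configs = (
            np.unique(self.u_all[:, : self.n_mod], axis=0)
            if self.u_all.size
            else np.zeros((1, 0))
        )
        self._build_param_map()

    def _build_param_map(self) -> None:
        spec, pr = self.spec, self.priors
        names: list[str] = []
        variances: list[float] = []
        regions = spec.regions
        self._a_idx = np.argwhere(spec.a_mask(include_diagonal=False))
        for i, j in self._a_idx:
            names.append(f"A[{regions[i]}<-{regions[j]}]")
            variances.append(pr.intrinsic_var)
        for r in regions:
            names.append(f"self[{r}]")
            variances.append(pr.self_var)
        self._b_idx = {}
        for m in spec.modulator_names:
            idx = np.argwhere(spec.b_mask(m))
            self._b_idx[m] = idx
            for i, j in idx:
                names.append(b_param_name(m, regions[j], regions[i]))
                variances.append(pr.modulatory_var)
        self._c_idx = np.argwhere(spec.c_mask())
        for i, j in self._c_idx:
            names.append(f"C[{regions[i]}<-{spec.driving_names[j]}]")
            variances.append(pr.driving_var)
        for key in pr.hemo_free:
            if key not in HEMO_DEFAULTS:
                raise ValueError(f"unknown hemodynamic parameter {key!r}")
            names.append(f"hemo[{key}]")
            variances.append(pr.hemo_var)
        self.param_names = names
        self.prior_mean = np.zeros(len(names))
        self.prior_var = np.asarray(variances, dtype=float)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def matrices(self, theta: np.ndarray):
        """Assemble (A, B_stack, C, hemo arrays) from a parameter vector."""
        spec = self.spec
        n = spec.n_regions
        k = 0
        A = np.zeros((n, n))
        for i, j in self._a_idx:
            A[i, j] = theta[k]
            k += 1
        for r in range(n):
            A[r, r] = _SELF_SCALE * np.exp(theta[k])
            k += 1
        b_stack = np.zeros((self.n_mod, n, n))
        for mi, m in enumerate(spec.modulator_names):
            for i, j in self._b_idx[m]:
                b_stack[mi, i, j] = theta[k]
                k += 1
        C = np.zeros((n, len(spec.driving_names)))
        for i, j in self._c_idx:
            C[i, j] = theta[k]
            k += 1
        hemo = {key: np.full(n, val) for key, val in HEMO_DEFAULTS.items()}
        for key in self.priors.hemo_free:
            hemo[key] = hemo[key] * np.exp(theta[k])
            k += 1
        return A, b_stack, C, hemo

    def stable(self, A: np.ndarray, b_stack: np.ndarray) -> bool:
        for cfg in self._configs:
            M = A.copy()
            for j, uj in enumerate(cfg):
                if uj:
                    M = M + uj * b_stack[j]
            if np.max(np.linalg.eigvals(M).real) >= 0:
                return False
        return True

    def predict(self, theta: np.ndarray) -> np.ndarray | None:
        """Noiseless BOLD (n_volumes x n_regions), or None if unstable."""
        A, b_stack, C, hemo = self.matrices(theta)
        if not self.stable(A, b_stack):
            return None
        return _integrate_bold(
            self.u_all,
            self.n_mod,
            np.ascontiguousarray(A),
            np.ascontiguousarray(b_stack),
            np.ascontiguousarray(C),
            hemo["kappa"], hemo["gamma"], hemo["tau"],
            hemo["alpha"], hemo["E0"], hemo["epsilon"],
            self.inputs.dt_s,
            self.design.microtime_bins_per_tr,
            self.design.n_volumes,
        )

    def to_parameters(self, theta: np.ndarray) -> DCMParameters:
        A, b_stack, C, hemo = self.matrices(theta)
        B = {m: b_stack[i] for i, m in enumerate(self.spec.modulator_names)}
        return DCMParameters(spec=self.spec, A=A, B=B, C=C, hemo=hemo)


# -- the variational-Laplace engine -----------------------------------------


def _projector(n: int, confounds: np.ndarray | None) -> tuple[np.ndarray | None, int]:
    if confounds is None:
        return None, 0
    X0 = np.asarray(confounds, dtype=float)
    rank = np.linalg.matrix_rank(X0)
    return X0 @ np.linalg.pinv(X0), rank


def variational_laplace(
    predict,
    y: np.ndarray,
    prior_mean: np.ndarray,
    prior_var: np.ndarray,
    *,
    confounds: np.ndarray | None = None,
    fixed_noise_precision: float | None = None,
    max_iter: int = 64,
    tol: float = 1e-2,
    tol_streak: int = 3,
    fd_step: float = 1e-3,
    fd_mode: str = "central",
    max_step_trials: int = 8,
    theta_init: np.ndarray | None = None,
) -> InversionResult:
    """Gauss-Newton / EM ascent on the free energy for any forward map.

    ``predict(theta)`` returns an array broadcastable to ``y`` (or None for
    an inadmissible theta). Parameters with zero prior variance are pinned
    at their prior mean. Convergence: |dF| < tol for ``tol_streak``
    consecutive accepted iterations.

    ``fd_mode`` controls the finite-difference Jacobian: ``"central"``
    (default; two extra passes per parameter), ``"forward"`` (one, cheaper
    but prone to stalling in shallow basins), or ``"hybrid"`` (a forward
    phase followed by a central polish).
    """
    if fd_mode not in ("forward", "central", "hybrid"):
        raise ValueError("fd_mode must be 'forward', 'central' or 'hybrid'")
    y = np.asarray(y, dtype=float)
    T = y.shape[0]
    P0_full, rank0 = _projector(T, confounds)

    def proj(arr: np.ndarray) -> np.ndarray:
        if P0_full is None:
            return arr.ravel()
        return (arr - P0_full @ arr).ravel()

    yp = proj(y)
    n_cols = 1 if y.ndim == 1 else y.shape[1]
    n_eff = y.size - rank0 * n_cols

    prior_mean = np.asarray(prior_mean, dtype=float)
    prior_var = np.asarray(prior_var, dtype=float)
    free = prior_var > 0
    p_free = int(free.sum())
    pv = prior_var[free]
    logdet_prior = float(np.sum(np.log(pv)))
    P0 = np.diag(1.0 / pv)

    def predict_full(theta_free: np.ndarray) -> np.ndarray | None:
        theta = prior_mean.copy()
        theta[free] = theta_free
        return predict(theta)

    mode = ["central" if fd_mode == "central" else "forward"]

    def jacobian(theta_free: np.ndarray, g0p: np.ndarray | None = None) -> np.ndarray:
        J = np.zeros((yp.size, p_free))
        h = fd_step
        if mode[0] == "forward" and g0p is None:
            g0 = predict_full(theta_free)
            g0p = proj(g0) if g0 is not None else None
        for i in range(p_free):
            tp = theta_free.copy(); tp[i] += h
            gp = predict_full(tp)
            if mode[0] == "forward" and gp is not None and g0p is not None:
                J[:, i] = (proj(gp) - g0p) / h
                continue
            tm = theta_free.copy(); tm[i] -= h
            gm = predict_full(tm)
            if gp is not None and gm is not None:
                J[:, i] = (proj(gp) - proj(gm)) / (2 * h)
            elif gp is not None or gm is not None:
                g_mid = predict_full(theta_free)
                if g_mid is None:
                    continue
                if gp is not None:
                    J[:, i] = (proj(gp) - proj(g_mid)) / h
                else:
                    J[:, i] = (proj(g_mid) - proj(gm)) / h
        return J

    def noise_update(err2: float, JtJ: np.ndarray, pi: float) -> tuple[float, np.ndarray]:
        for _ in range(4):
            C = np.linalg.inv(pi * JtJ + P0)
            if fixed_noise_precision is None:
                pi = n_eff / (err2 + float(np.trace(JtJ @ C)))
        return pi, C

    def f_value(err2: float, delta: np.ndarray, pi: float, C: np.ndarray) -> float:
        sign, logdet_c = np.linalg.slogdet(C)
        if sign <= 0:
            return -np.inf
        return float(
            -0.5 * pi * err2
            + 0.5 * n_eff * (np.log(pi) - np.log(2 * np.pi))
            - 0.5 * float(delta @ (delta / pv))
            + 0.5 * (logdet_c - logdet_prior)
        )

    if theta_init is None:
        theta = prior_mean[free].copy()
    else:
        theta = np.asarray(theta_init, dtype=float)[free].copy()
    g = predict_full(theta)
    if g is None and theta_init is not None:
        theta = prior_mean[free].copy()
        g = predict_full(theta)
    if g is None:
        raise ValueError("forward model inadmissible at the starting point")
    e = yp - proj(g)
    err2 = float(e @ e)
    pi = fixed_noise_precision if fixed_noise_precision is not None else n_eff / max(err2, 1e-12)
    J = jacobian(theta, yp - e)
    JtJ = J.T @ J
    pi, C = noise_update(err2, JtJ, pi)
    F = f_value(err2, theta - prior_mean[free], pi, C)

    trace = [F]
    messages: list[str] = []
    damping = 1.0
    streak = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad = pi * (J.T @ e) - (theta - prior_mean[free]) / pv
        H = pi * JtJ + P0
        accepted = False
        for _ in range(max_step_trials):
            scale = damping * np.mean(np.diag(H))
            try:
                step = np.linalg.solve(H + scale * np.eye(p_free), grad)
            except np.linalg.LinAlgError:
                damping *= 4.0
                continue
            theta_c = theta + step
            g_c = predict_full(theta_c)
            if g_c is None:
                damping *= 4.0
                continue
            e_c = yp - proj(g_c)
            err2_c = float(e_c @ e_c)
            # cheap pre-screen with the current curvature
            F_pre = f_value(err2_c, theta_c - prior_mean[free], pi, C)
            if not np.isfinite(F_pre):
                raise FloatingPointError(
                    f"non-finite free energy at iteration {it} "
                    f"(err2={err2_c:.3g}, pi={pi:.3g})"
                )
            if F_pre < F - 1e-9:
                damping *= 4.0
                continue
            # full evaluation with refreshed curvature and noise precision
            J_c = jacobian(theta_c, yp - e_c)
            JtJ_c = J_c.T @ J_c
            pi_c, C_c = noise_update(err2_c, JtJ_c, pi)
            F_c = f_value(err2_c, theta_c - prior_mean[free], pi_c, C_c)
            if F_c >= F - 1e-9:
                theta, g, e, err2 = theta_c, g_c, e_c, err2_c
                J, JtJ, pi, C = J_c, JtJ_c, pi_c, C_c
                dF = F_c - F
                F = max(F_c, F)
                damping = max(damping * 0.4, 1e-8)
                accepted = True
                break
            damping *= 4.0
        def _switch_to_central() -> None:
            # central-difference polish: recompute curvature at the current
            # point with the accurate Jacobian and keep iterating
            nonlocal J, JtJ, pi, C, F, streak, damping
            mode[0] = "central"
            J = jacobian(theta, yp - e)
            JtJ = J.T @ J
            pi, C = noise_update(err2, JtJ, pi)
            F = f_value(err2, theta - prior_mean[free], pi, C)
            streak = 0
            damping = 1.0

        if not accepted:
            if fd_mode == "hybrid" and mode[0] == "forward":
                _switch_to_central()
                continue
            messages.append(f"no acceptable step at iteration {it}; stopping")
            converged = streak > 0 or it > 1
            break
        if F >= trace[-1]:
            # re-linearization at the central-difference switch can shift F
            # slightly; the trace records the advancing accepted values
            trace.append(F)
        streak = streak + 1 if dF < tol else 0
        if streak >= tol_streak:
            if fd_mode == "hybrid" and mode[0] == "forward":
                _switch_to_central()
                continue
            converged = True
            break
    else:
        messages.append(f"reached max_iter={max_iter} without convergence")

    mean = prior_mean.copy()
    mean[free] = theta
    cov = np.zeros((prior_mean.size, prior_mean.size))
    C_sym = 0.5 * (C + C.T)
    cov[np.ix_(free, free)] = C_sym
    return InversionResult(
        param_names=[f"theta[{i}]" for i in range(prior_mean.size)],
        posterior_mean=mean,
        posterior_cov=cov,
        free_energy=F,
        trace=trace,
        converged=converged,
        n_iter=it,
        noise_precision=pi,
        messages=messages,
    )


def invert(
    spec: DCMSpec,
    data,
    design: TaskDesign,
    priors: PriorSpec | None = None,
    *,
    microtime_bins: int | None = None,
    drift_order: int = 2,
    max_iter: int = 64,
    tol: float = 1e-2,
    fd_step: float = 1e-3,
    fd_mode: str = "central",
    theta_init: dict[str, float] | None = None,
) -> InversionResult:
    """Fit one DCM to one subject's region time series.

    ``data`` is a :class:`~emoconn.generative_model.BoldTimeSeries` or a
    T x n array in the spec's region order. Legendre confounds up to
    ``drift_order`` are projected out of data and prediction. Deterministic
    given its inputs.

    ``theta_init`` optionally warm-starts the ascent from a named parameter
    map (typically the posterior of a richer reference model); parameters
    absent from the map start at their prior mean. Warm-starting matters
    for multi-edge modulatory models, whose cold ascent from the zero prior
    mean can stall against the stability boundary and understate their
    evidence.
    """
    priors = priors or PriorSpec()
    y = data.data if hasattr(data, "data") else np.asarray(data, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("data contain non-finite values")
    if y.shape[0] != design.n_volumes:
        raise ValueError("data length does not match design n_volumes")
    fwd = DCMForward(spec, design, priors, microtime_bins=microtime_bins)
    confounds = legendre_drift_basis(design.n_volumes, drift_order)
    init_vec = None
    if theta_init is not None:
        init_vec = np.array([theta_init.get(nm, 0.0) for nm in fwd.param_names])
    result = variational_laplace(
        fwd.predict,
        y,
        fwd.prior_mean,
        fwd.prior_var,
        confounds=confounds,
        fixed_noise_precision=priors.fixed_noise_precision,
        max_iter=max_iter,
        tol=tol,
        fd_step=fd_step,
        fd_mode=fd_mode,
        theta_init=init_vec,
    )
    result.param_names = fwd.param_names
    return result


def log_evidence(result: InversionResult) -> float:
    """The free-energy approximation to log model evidence (nats)."""
    if not result.converged:
        warnings.warn(
            "inversion did not converge; free energy may be unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    return result.free_energy
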