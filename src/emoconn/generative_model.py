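"""Bilinear neural dynamics with a balloon-windkessel BOLD observation model.

This is the forward model shared by the simulator and the model inversion:

* neural states ``x`` (one per region) follow the bilinear equation
  ``dx/dt = (A + sum_j u_j B_j) x + C u``, where ``A`` holds intrinsic
  coupling rates (Hz), each ``B_j`` the change in coupling induced by
  modulatory input ``u_j``, and ``C`` the gains of driving inputs;
* each region's hemodynamics follow the balloon-windkessel equations in
  vasodilatory signal ``s``, normalized flow ``f``, venous volume ``v`` and
  deoxyhemoglobin content ``q``;
* the BOLD observation is the classic volume/deoxyhemoglobin mixture
  ``y = V0 [k1 (1-q) + k2 (1-q/v) + k3 (1-v)]`` with 1.5-T coefficients,
  reported in percent-signal-change-like units.

Because the task inputs are boxcars, the neural subsystem is piecewise
linear-time-invariant: the integrator uses the exact matrix-exponential
propagator of each distinct input configuration per microtime bin, and RK4
for the hemodynamic states driven by the linearly interpolated neural
trajectory. The time loop is numba-compiled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "HEMO_DEFAULTS",
    "DEFAULT_REGIONS",
    "DCMSpec",
    "DCMParameters",
    "BoldTimeSeries",
    "neural_derivative",
    "hemodynamic_derivative",
    "bold_observation",
    "integrate_and_sample",
    "legendre_drift_basis",
]

#: Canonical region order of the face-processing network.
DEFAULT_REGIONS = ("V1", "FG", "AMY", "OFC")

#: Default hemodynamic constants (per region): signal decay kappa (1/s),
#: autoregulation gamma (1/s), mean transit time tau (s), vessel stiffness
#: alpha, resting oxygen extraction E0, and BOLD signal scale epsilon.
HEMO_DEFAULTS = {
    "kappa": 0.64,
    "gamma": 0.32,
    "tau": 2.0,
    "alpha": 0.32,
    "E0": 0.4,
    "epsilon": 1.0,
}

_V0 = 0.04          # resting venous blood volume fraction
_BOLD_SCALE = 100.0  # report in percent-signal-change-like units

Edge = tuple[str, str]


@dataclass(frozen=True)
class DCMSpec:
    """Network architecture: which connections exist and which are modulated.

    Edges are ordered ``(source, target)`` region-label pairs. Every
    modulated edge must be an intrinsic edge; driving-input targets must be
    regions (the study drives V1 only with the all-faces input).
    """

    regions: tuple[str, ...] = DEFAULT_REGIONS
    intrinsic_edges: frozenset[Edge] = frozenset()
    modulated_edges: dict[str, frozenset[Edge]] = field(default_factory=dict)
    driving_inputs: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        regions = set(self.regions)
        for src, dst in self.intrinsic_edges:
            if src not in regions or dst not in regions:
                raise ValueError(f"intrinsic edge ({src}, {dst}) uses unknown region")
            if src == dst:
                raise ValueError("self-connections are implicit; do not list them")
        for name, edges in self.modulated_edges.items():
            extra = set(edges) - set(self.intrinsic_edges)
            if extra:
                raise ValueError(
                    f"modulator {name!r} modulates non-intrinsic edges {sorted(extra)}"
                )
        for name, targets in self.driving_inputs.items():
            if not set(targets) <= regions:
                raise ValueError(f"driving input {name!r} targets unknown regions")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def modulator_names(self) -> tuple[str, ...]:
        return tuple(sorted(self.modulated_edges))

    @property
    def driving_names(self) -> tuple[str, ...]:
        return tuple(sorted(self.driving_inputs))

    def index(self, region: str) -> int:
        return self.regions.index(region)

    def _mask(self, edges) -> np.ndarray:
        m = np.zeros((self.n_regions, self.n_regions), dtype=bool)
        for src, dst in edges:
            m[self.index(dst), self.index(src)] = True
        return m

    def a_mask(self, include_diagonal: bool = True) -> np.ndarray:
        m = self._mask(self.intrinsic_edges)
        if include_diagonal:
            np.fill_diagonal(m, True)
        return m

    def b_mask(self, modulator: str) -> np.ndarray:
        return self._mask(self.modulated_edges[modulator])

    def c_mask(self) -> np.ndarray:
        m = np.zeros((self.n_regions, len(self.driving_names)), dtype=bool)
        for j, name in enumerate(self.driving_names):
            for region in self.driving_inputs[name]:
                m[self.index(region), j] = True
        return m


def _hemo_array(hemo: dict, key: str, n: int) -> np.ndarray:
    val = np.asarray(hemo.get(key, HEMO_DEFAULTS[key]), dtype=float)
    return np.broadcast_to(val, (n,)).copy()


@dataclass
class DCMParameters:
    """Numeric parameterization of a :class:`DCMSpec`.

    ``A`` (n x n, Hz) with ``A[i, j]`` the rate of influence of region j on
    region i; ``B`` maps modulator name to its n x n rate matrix; ``C``
    (n x n_driving, Hz) columns follow ``spec.driving_names``. ``hemo`` maps
    each balloon constant to a per-region array. ``drift_coeffs`` holds
    Legendre drift coefficients (order x region).
    """

    spec: DCMSpec
    A: np.ndarray
    B: dict[str, np.ndarray]
    C: np.ndarray
    hemo: dict[str, np.ndarray] = field(default_factory=dict)
    noise_sd: float = 0.0
    drift_coeffs: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.spec.n_regions
        self.A = np.asarray(self.A, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if self.A.shape != (n, n):
            raise ValueError(f"A must be {n}x{n}")
        if self.C.shape != (n, len(self.spec.driving_names)):
            raise ValueError("C shape inconsistent with spec.driving_names")
        if np.any(self.A[~self.spec.a_mask()] != 0):
            raise ValueError("A has nonzero entries off the intrinsic structure")
        if np.any(np.diag(self.A) >= 0):
            raise ValueError("diagonal of A must be strictly negative")
        for name in self.spec.modulator_names:
            bmat = np.asarray(self.B[name], dtype=float)
            if bmat.shape != (n, n):
                raise ValueError(f"B[{name!r}] must be {n}x{n}")
            if np.any(bmat[~self.spec.b_mask(name)] != 0):
                raise ValueError(f"B[{name!r}] nonzero off its modulated edges")
            self.B[name] = bmat
        if np.any(self.C[~self.spec.c_mask()] != 0):
            raise ValueError("C has nonzero entries off the driving structure")
        self.hemo = {k: _hemo_array(self.hemo, k, n) for k in HEMO_DEFAULTS}
        for key in ("kappa", "gamma", "tau", "alpha", "E0", "epsilon"):
            if np.any(self.hemo[key] <= 0):
                raise ValueError(f"hemodynamic parameter {key} must be positive")
        if np.any(self.hemo["E0"] >= 1):
            raise ValueError("E0 must lie in (0, 1)")
        if np.any(self.hemo["alpha"] >= 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def coupling_at(self, u_mod: dict[str, float]) -> np.ndarray:
        """Effective coupling matrix A + sum_j u_j B_j."""
        M = self.A.copy()
        for name, val in u_mod.items():
            if val:
                M = M + val * self.B[name]
        return M


@dataclass(frozen=True)
class BoldTimeSeries:
    """Sampled BOLD data, one column per region."""

    data: np.ndarray
    tr_s: float
    regions: tuple[str, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2 or data.shape[1] != len(self.regions):
            raise ValueError("data must be T x n_regions")
        if not np.all(np.isfinite(data)):
            raise ValueError("BOLD data contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    def series(self, region: str) -> np.ndarray:
        return self.data[:, self.regions.index(region)]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.data, columns=list(self.regions))
        df.insert(0, "time_s", np.arange(self.n_volumes) * self.tr_s)
        return df


# -- the model equations (reference / oracle form) --------------------------


def neural_derivative(
    x: np.ndarray, u: dict[str, float], params: DCMParameters
) -> np.ndarray:
    """dx/dt = (A + sum_j u_j B_j) x + C u for one time point.

    ``u`` maps input names (modulators and driving inputs) to values.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (params.spec.n_regions,):
        raise ValueError("state dimension inconsistent with spec")
    M = params.coupling_at({k: u.get(k, 0.0) for k in params.spec.modulator_names})
    drive = np.array([u.get(k, 0.0) for k in params.spec.driving_names])
    return M @ x + params.C @ drive


def hemodynamic_derivative(
    h: np.ndarray, x: np.ndarray, hemo: dict[str, np.ndarray]
) -> np.ndarray:
    """Balloon-windkessel derivatives for states ``h = [s, f, v, q]`` rows.

    ds/dt = x - kappa s - gamma (f - 1); df/dt = s;
    dv/dt = (f - v^(1/alpha)) / tau;
    dq/dt = (f E(f, E0)/E0 - v^(1/alpha) q/v) / tau,
    with E(f, E0) = 1 - (1 - E0)^(1/f).
    """
    h = np.asarray(h, dtype=float)
    s, f, v, q = h
    if np.any(f <= 0) or np.any(v <= 0) or np.any(q <= 0):
        raise ValueError("f, v and q must be strictly positive")
    kappa, gam, tau = hemo["kappa"], hemo["gamma"], hemo["tau"]
    alpha, e0 = hemo["alpha"], hemo["E0"]
    fout = v ** (1.0 / alpha)
    extraction = 1.0 - (1.0 - e0) ** (1.0 / f)
    return np.stack(
        [
            x - kappa * s - gam * (f - 1.0),
            s,
            (f - fout) / tau,
            (f * extraction / e0 - fout * q / v) / tau,
        ]
    )


def bold_coefficients(e0: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """1.5-T k-coefficients: k1 = 7 E0, k2 = 2, k3 = 2 E0 - 0.2."""
    e0 = np.asarray(e0, dtype=float)
    return 7.0 * e0, np.full_like(e0, 2.0), 2.0 * e0 - 0.2


def bold_observation(v: np.ndarray, q: np.ndarray, hemo: dict) -> np.ndarray:
    """BOLD signal from venous volume and deoxyhemoglobin content."""
    v = np.asarray(v, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(v <= 0) or np.any(q <= 0):
        raise ValueError("v and q must be strictly positive")
    k1, k2, k3 = bold_coefficients(hemo["E0"])
    eps = np.asarray(hemo.get("epsilon", 1.0), dtype=float)
    return _BOLD_SCALE * _V0 * eps * (k1 * (1 - q) + k2 * (1 - q / v) + k3 * (1 - v))


# -- fast integrator --------------------------------------------------------


@njit(cache=True, fastmath=True)
def _expm_affine(M, c, dt, Phi, b):
    """exp(dt*[[M, c],[0, 0]]) via scaled Taylor series, written into
    ``Phi`` and ``b`` so that x(dt) = Phi x(0) + b for dx/dt = M x + c."""
    n = M.shape[0]
    m = n + 1
    G = np.zeros((m, m))
    for i in range(n):
        for j in range(n):
            G[i, j] = M[i, j] * dt
        G[i, n] = c[i] * dt
    nrm = np.abs(G).sum()
    squarings = 0
    while nrm > 0.25:
        nrm *= 0.5
        squarings += 1
    G /= 2.0 ** squarings
    E = np.eye(m)
    term = np.eye(m)
    tmp = np.empty((m, m))
    for k in range(1, 13):
        # term = term @ G / k
        for i in range(m):
            for j in range(m):
                acc = 0.0
                for l in range(m):
                    acc += term[i, l] * G[l, j]
                tmp[i, j] = acc / k
        for i in range(m):
            for j in range(m):
                term[i, j] = tmp[i, j]
                E[i, j] += tmp[i, j]
    for _ in range(squarings):
        for i in range(m):
            for j in range(m):
                acc = 0.0
                for l in range(m):
                    acc += E[i, l] * E[l, j]
                tmp[i, j] = acc
        for i in range(m):
            for j in range(m):
                E[i, j] = tmp[i, j]
    for i in range(n):
        for j in range(n):
            Phi[i, j] = E[i, j]
        b[i] = E[i, n]


@njit(cache=True, fastmath=True)
def _integrate_bold(
    u_all,      # (n_bins, n_inputs): modulators then driving columns
    n_mod,      # number of modulator columns
    A, B_stack, C,
    kappa, gam, tau, alpha, e0, eps,
    dt, bins_per_tr, n_volumes,
):
    n = A.shape[0]
    n_bins = u_all.shape[0]
    n_in = u_all.shape[1]
    n_drive = n_in - n_mod
    x = np.zeros(n)
    x_new = np.zeros(n)
    s = np.zeros(n)
    f = np.ones(n)
    v = np.ones(n)
    q = np.ones(n)
    y = np.zeros((n_volumes, n))

    k1 = 7.0 * e0
    k3 = 2.0 * e0 - 0.2
    inv_alpha = 1.0 / alpha

    M = np.empty((n, n))
    c = np.empty(n)
    Phi = np.eye(n)
    b = np.zeros(n)
    Phi_h = np.eye(n)
    b_h = np.zeros(n)
    x_half = np.zeros(n)
    # finite sentinel: fastmath assumes no NaNs, so NaN compares are unsafe
    prev = np.full(n_in, -1.7e308)
    vol = 0
    for k in range(n_bins):
        changed = False
        for j in range(n_in):
            if u_all[k, j] != prev[j]:
                changed = True
                break
        if changed:
            for j in range(n_in):
                prev[j] = u_all[k, j]
            for i in range(n):
                for j in range(n):
                    M[i, j] = A[i, j]
            for j in range(n_mod):
                uj = u_all[k, j]
                if uj != 0.0:
                    for i in range(n):
                        for l in range(n):
                            M[i, l] += uj * B_stack[j, i, l]
            for i in range(n):
                acc = 0.0
                for j in range(n_drive):
                    acc += C[i, j] * u_all[k, n_mod + j]
                c[i] = acc
            _expm_affine(M, c, dt, Phi, b)
            _expm_affine(M, c, 0.5 * dt, Phi_h, b_h)

        if k % bins_per_tr == 0 and vol < n_volumes:
            for r in range(n):
                y[vol, r] = (
                    _BOLD_SCALE
                    * _V0
                    * eps[r]
                    * (k1[r] * (1 - q[r]) + 2.0 * (1 - q[r] / v[r]) + k3[r] * (1 - v[r]))
                )
            vol += 1

        for i in range(n):
            acc = b[i]
            acc_h = b_h[i]
            for j in range(n):
                acc += Phi[i, j] * x[j]
                acc_h += Phi_h[i, j] * x[j]
            x_new[i] = acc
            x_half[i] = acc_h

        # RK4 for hemodynamics; the neural trajectory is exact at the bin
        # endpoints and midpoint (matrix-exponential propagators)
        for r in range(n):
            sr, fr, vr, qr = s[r], f[r], v[r], q[r]
            x0 = x[r]
            xh = x_half[r]
            x1 = x_new[r]
            kp, gm, tu = kappa[r], gam[r], tau[r]
            ia, er = inv_alpha[r], e0[r]

            # k1 stage
            fo = vr ** ia
            ex = 1.0 - (1.0 - er) ** (1.0 / fr)
            d1s = x0 - kp * sr - gm * (fr - 1.0)
            d1f = sr
            d1v = (fr - fo) / tu
            d1q = (fr * ex / er - fo * qr / vr) / tu
            # k2 stage
            s2 = sr + 0.5 * dt * d1s
            f2 = max(fr + 0.5 * dt * d1f, 1e-8)
            v2 = max(vr + 0.5 * dt * d1v, 1e-8)
            q2 = max(qr + 0.5 * dt * d1q, 1e-8)
            fo = v2 ** ia
            ex = 1.0 - (1.0 - er) ** (1.0 / f2)
            d2s = xh - kp * s2 - gm * (f2 - 1.0)
            d2f = s2
            d2v = (f2 - fo) / tu
            d2q = (f2 * ex / er - fo * q2 / v2) / tu
            # k3 stage
            s3 = sr + 0.5 * dt * d2s
            f3 = max(fr + 0.5 * dt * d2f, 1e-8)
            v3 = max(vr + 0.5 * dt * d2v, 1e-8)
            q3 = max(qr + 0.5 * dt * d2q, 1e-8)
            fo = v3 ** ia
            ex = 1.0 - (1.0 - er) ** (1.0 / f3)
            d3s = xh - kp * s3 - gm * (f3 - 1.0)
            d3f = s3
            d3v = (f3 - fo) / tu
            d3q = (f3 * ex / er - fo * q3 / v3) / tu
            # k4 stage
            s4 = sr + dt * d3s
            f4 = max(fr + dt * d3f, 1e-8)
            v4 = max(vr + dt * d3v, 1e-8)
            q4 = max(qr + dt * d3q, 1e-8)
            fo = v4 ** ia
            ex = 1.0 - (1.0 - er) ** (1.0 / f4)
            d4s = x1 - kp * s4 - gm * (f4 - 1.0)
            d4f = s4
            d4v = (f4 - fo) / tu
            d4q = (f4 * ex / er - fo * q4 / v4) / tu

            s[r] = sr + dt / 6.0 * (d1s + 2 * d2s + 2 * d3s + d4s)
            f[r] = max(fr + dt / 6.0 * (d1f + 2 * d2f + 2 * d3f + d4f), 1e-8)
            v[r] = max(vr + dt / 6.0 * (d1v + 2 * d2v + 2 * d3v + d4v), 1e-8)
            q[r] = max(qr + dt / 6.0 * (d1q + 2 * d2q + 2 * d3q + d4q), 1e-8)

        for i in range(n):
            x[i] = x_new[i]
    return y


def _input_matrix(spec: DCMSpec, inputs, n_bins: int) -> np.ndarray:
    """Stack modulator then driving input columns on the microtime grid."""
    cols = []
    for name in spec.modulator_names:
        cols.append(inputs.by_name(name)[:n_bins])
    for name in spec.driving_names:
        cols.append(inputs.by_name(name)[:n_bins])
    if not cols:
        return np.zeros((n_bins, 0))
    return np.column_stack(cols)


def check_stability(params: DCMParameters, u_all: np.ndarray) -> None:
    """Raise if A + sum u_j B_j is unstable for any attained configuration."""
    spec = params.spec
    n_mod = len(spec.modulator_names)
    configs = np.unique(u_all[:, :n_mod], axis=0) if u_all.size else np.zeros((1, 0))
    for cfg in configs:
        M = params.coupling_at(dict(zip(spec.modulator_names, cfg)))
        eigs = np.linalg.eigvals(M)
        worst = eigs[np.argmax(eigs.real)]
        if worst.real >= 0:
            raise ValueError(
                f"unstable coupling for modulator configuration {cfg.tolist()}: "
                f"eigenvalue {worst:.4f} has non-negative real part"
            )


def integrate_and_sample(
    spec: DCMSpec,
    params: DCMParameters,
    inputs,
    design,
    rng: np.random.Generator | None = None,
) -> BoldTimeSeries:
    """Integrate the DCM on the microtime grid and sample BOLD at TR.

    Observation noise (``params.noise_sd``) is added only when ``rng`` is
    given; polynomial drift is added whenever ``params.drift_coeffs`` is
    set. Deterministic given the rng seed.
    """
    n_bins = design.n_volumes * design.microtime_bins_per_tr
    u_all = _input_matrix(spec, inputs, n_bins)
    check_stability(params, u_all)
    n_mod = len(spec.modulator_names)
    b_stack = (
        np.stack([params.B[m] for m in spec.modulator_names])
        if n_mod
        else np.zeros((0, spec.n_regions, spec.n_regions))
    )
    y = _integrate_bold(
        np.ascontiguousarray(u_all, dtype=float),
        n_mod,
        np.ascontiguousarray(params.A),
        np.ascontiguousarray(b_stack),
        np.ascontiguousarray(params.C),
        params.hemo["kappa"],
        params.hemo["gamma"],
        params.hemo["tau"],
        params.hemo["alpha"],
        params.hemo["E0"],
        params.hemo["epsilon"],
        inputs.dt_s,
        design.microtime_bins_per_tr,
        design.n_volumes,
    )
    if params.drift_coeffs is not None:
        basis = legendre_drift_basis(design.n_volumes, params.drift_coeffs.shape[0] - 1)
        y = y + basis @ params.drift_coeffs
    if rng is not None and params.noise_sd > 0:
        y = y + rng.normal(0.0, params.noise_sd, size=y.shape)
    return BoldTimeSeries(data=y, tr_s=design.tr_s, regions=spec.regions)


def legendre_drift_basis(n_volumes: int, order: int = 2) -> np.ndarray:
    """Legendre polynomials P0..P_order evaluated on [-1, 1] over volumes."""
    t = np.linspace(-1.0, 1.0, n_volumes)
    return np.polynomial.legendre.legvander(t, order)
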