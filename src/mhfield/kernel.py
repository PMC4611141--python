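"""Difference-of-Gaussians (Mexican-hat) lateral connectivity.

The lateral weight field is built from a difference of two Gaussians: a
narrow excitatory lobe of amplitude ``1 + beta`` and standard deviation
``sigma``, minus a wider inhibitory lobe of amplitude ``beta`` and standard
deviation ``K * sigma``.  The two lobes are kept as separate non-negative
fields ``w_e`` and ``w_i`` because they drive separate synaptic channels;
the *net* lateral weight seen by a neighbour at offset ``d`` is

    net(d) = alpha_e * w_e(d) - alpha_i * w_i(d)

which peaks at ``alpha_e`` at the origin (since ``(1+beta) - beta = 1``)
and has a negative inhibitory ring whenever ``K > 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "KernelSpec",
    "KernelField",
    "preset",
    "PRESETS",
    "build_kernel",
    "kernel_minimum",
    "kernel_zero_crossing",
    "net_radial",
]

#: Named Mexican-hat variants.  All share alpha_e = alpha_i = 200 and an
#: isotropic sigma of 5 cells (the single-stimulus protocols); the
#: two-stimulus protocols rebuild them with sigma = 8.5.
_PRESET_PARAMS = {
    "s1": dict(K=1.2, beta=6.0),
    "s2": dict(K=2.0, beta=1.43),
    "s3": dict(K=1.2, beta=8.0),
}


@dataclass(frozen=True)
class KernelSpec:
    """Parameters of the difference-of-Gaussians lateral kernel.

    ``normalization`` selects the weight convention:

    - ``"raw"``: ``w_e`` is the first Gaussian term (peak ``1 + beta``) and
      ``w_i`` the second (peak ``beta``).  The net kernel then spans
      ``[about -0.57 * alpha, alpha]`` for the reference variant.
    - ``"peak"``: both terms divided by ``1 + beta`` so that ``w_e`` peaks
      at exactly 1.
    - ``"net-split"``: the net difference-of-Gaussians (which already spans
      about [-0.57, 1]) is split into its positive part (-> ``w_e``) and the
      magnitude of its negative part (-> ``w_i``).  Excitation and
      inhibition then act on disjoint rings, which is what makes the field
      bistable between the all-off state and a localised spiking cluster:
      with the overlapping raw terms the slower inhibitory channel always
      outweighs excitation in the long run and no cluster survives.  This
      is the package default (see the methods note on calibration).
    """

    sigma_x: float
    sigma_y: float
    K: float
    beta: float
    alpha_e: float = 200.0
    alpha_i: float = 200.0
    mu_x: float = 0.0
    mu_y: float = 0.0
    normalization: str = "raw"

    def __post_init__(self) -> None:
        for name in ("sigma_x", "sigma_y", "K", "beta", "alpha_e", "alpha_i",
                     "mu_x", "mu_y"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"KernelSpec.{name} must be finite, got {v!r}")
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("sigma_x and sigma_y must be positive")
        if self.K < 1.0:
            raise ValueError("K must be >= 1 (inhibition at least as wide as excitation)")
        if self.beta < 0 or self.alpha_e < 0 or self.alpha_i < 0:
            raise ValueError("beta, alpha_e and alpha_i must be non-negative")
        if self.normalization not in ("raw", "peak", "net-split"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def amplitude_e(self) -> float:
        """Peak of the excitatory Gaussian term before gain scaling."""
        a = 1.0 + self.beta
        return a if self.normalization == "raw" else 1.0 if self.normalization == "peak" else a

    @property
    def amplitude_i(self) -> float:
        """Peak of the inhibitory Gaussian term before gain scaling."""
        b = self.beta
        return b / (1.0 + self.beta) if self.normalization == "peak" else b

    def with_sigma(self, sigma: float) -> "KernelSpec":
        return replace(self, sigma_x=sigma, sigma_y=sigma)


def preset(name: str, sigma: float = 5.0, normalization: str = "net-split") -> KernelSpec:
    """Return one of the named kernel variants (``s1``, ``s2``, ``s3``).

    Presets default to the calibrated ``net-split`` weight convention used
    by all protocol code; pass ``normalization="raw"`` for the raw
    Gaussian-term fields.
    """
    key = name.lower()
    if key not in _PRESET_PARAMS:
        raise KeyError(f"unknown kernel preset {name!r}; expected one of {sorted(_PRESET_PARAMS)}")
    p = _PRESET_PARAMS[key]
    return KernelSpec(sigma_x=sigma, sigma_y=sigma, K=p["K"], beta=p["beta"],
                      normalization=normalization)


PRESETS = {name: preset(name) for name in _PRESET_PARAMS}


@dataclass(frozen=True)
class KernelField:
    """Lateral weight fields sampled on integer cell offsets.

    ``w_e`` and ``w_i`` are square arrays over offsets ``-R .. R`` in both
    axes (``R = support_radius``); entry ``[R + dx, R + dy]`` is the weight
    from a spiking cell onto the cell offset by ``(dx, dy)``.
    """

    spec: KernelSpec
    w_e: np.ndarray
    w_i: np.ndarray
    support_radius: int

    @property
    def net(self) -> np.ndarray:
        """Net lateral weight alpha_e * w_e - alpha_i * w_i."""
        return self.spec.alpha_e * self.w_e - self.spec.alpha_i * self.w_i

    def center_value(self) -> float:
        r = self.support_radius
        return float(self.net[r, r])


def _gauss_terms(spec: KernelSpec, dx: np.ndarray, dy: np.ndarray):
    ex = np.exp(-((dx - spec.mu_x) ** 2) / (2.0 * spec.sigma_x ** 2)
                - ((dy - spec.mu_y) ** 2) / (2.0 * spec.sigma_y ** 2))
    ix = np.exp(-((dx - spec.mu_x) ** 2) / (2.0 * (spec.K * spec.sigma_x) ** 2)
                - ((dy - spec.mu_y) ** 2) / (2.0 * (spec.K * spec.sigma_y) ** 2))
    if spec.normalization == "net-split":
        net = (1.0 + spec.beta) * ex - spec.beta * ix
        return np.maximum(net, 0.0), np.maximum(-net, 0.0)
    return spec.amplitude_e * ex, spec.amplitude_i * ix


def build_kernel(spec: KernelSpec, grid=(100, 100), support_radius: int | None = None,
                 truncate: bool = False, cutoff: float = 1e-4) -> KernelField:
    """Evaluate the kernel on all integer offsets within the support radius.

    By default the support covers the full grid (no truncation).  With
    ``truncate=True`` the radius is shrunk to the smallest ring outside of
    which ``|net| < cutoff * net(0, 0)``.
    """
    nx, ny = grid
    if support_radius is None:
        support_radius = max(nx, ny) - 1
    r = int(support_radius)
    off = np.arange(-r, r + 1, dtype=float)
    dx = off[:, None]
    dy = off[None, :]
    w_e, w_i = _gauss_terms(spec, dx, dy)
    if truncate:
        net = np.abs(spec.alpha_e * w_e - spec.alpha_i * w_i)
        center = net[r, r]
        dist = np.hypot(dx, dy)
        keep = net >= cutoff * center
        r_needed = int(np.ceil(dist[keep].max())) if keep.any() else 0
        if r_needed < r:
            sl = slice(r - r_needed, r + r_needed + 1)
            return KernelField(spec=spec, w_e=w_e[sl, sl].copy(),
                               w_i=w_i[sl, sl].copy(), support_radius=r_needed)
    return KernelField(spec=spec, w_e=w_e, w_i=w_i, support_radius=r)


def net_radial(spec: KernelSpec, d):
    """Continuous net kernel along a ray, for an isotropic centred spec."""
    _require_isotropic(spec)
    d = np.asarray(d, dtype=float)
    u = np.exp(-(d ** 2) / (2.0 * spec.sigma_x ** 2))
    ui = np.exp(-(d ** 2) / (2.0 * (spec.K * spec.sigma_x) ** 2))
    if spec.normalization == "net-split":
        net = (1.0 + spec.beta) * u - spec.beta * ui
        return spec.alpha_e * np.maximum(net, 0.0) - spec.alpha_i * np.maximum(-net, 0.0)
    return spec.alpha_e * spec.amplitude_e * u - spec.alpha_i * spec.amplitude_i * ui


def _require_isotropic(spec: KernelSpec) -> None:
    if spec.sigma_x != spec.sigma_y or spec.mu_x != 0 or spec.mu_y != 0:
        raise ValueError("radial analysis requires an isotropic, centred kernel")


def kernel_minimum(spec: KernelSpec) -> tuple[float, float]:
    """Depth and radius of the inhibitory trough of the continuous net kernel.

    Substituting ``u = exp(-d^2 / (2 sigma^2))`` turns the radial net kernel
    into ``a_e * u - a_i * u^(1/K^2)`` on ``u in (0, 1]``, which is minimised
    by 1-D bounded search.  Requires ``K > 1``: for ``K <= 1`` the net kernel
    has no negative lobe.
    """
    _require_isotropic(spec)
    if spec.K <= 1.0:
        raise ValueError("kernel has no negative trough for K <= 1")
    a_e = spec.alpha_e * spec.amplitude_e
    a_i = spec.alpha_i * spec.amplitude_i
    inv_k2 = 1.0 / spec.K ** 2

    def f(u: float) -> float:
        return a_e * u - a_i * u ** inv_k2

    res = minimize_scalar(f, bounds=(1e-12, 1.0), method="bounded",
                          options={"xatol": 1e-12})
    u_min = float(res.x)
    depth = float(res.fun)
    radius = spec.sigma_x * math.sqrt(-2.0 * math.log(u_min))
    return depth, radius


def kernel_zero_crossing(spec: KernelSpec) -> float:
    """Radius where the continuous net kernel changes sign (K > 1 only)."""
    _require_isotropic(spec)
    if spec.K <= 1.0:
        raise ValueError("kernel has no sign change for K <= 1")
    _, r_min = kernel_minimum(spec)
    return float(brentq(lambda d: net_radial(spec, d), 1e-9, r_min, xtol=1e-10))
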