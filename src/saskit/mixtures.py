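"""Form-factor mixture modelling for polydisperse multicomponent systems.

Implements orientationally averaged form factors for simple geometric
bodies (sphere, ellipsoid of revolution, cylinder, core-shell sphere),
size polydispersity by numerical averaging over Gaussian or Schulz size
distributions, a Gaussian electron-density bilayer model with a
paracrystalline lamellar stacking factor, the analytic Percus-Yevick
hard-sphere structure factor, and weighted nonlinear least-squares fitting
of mixture models to measured curves.

Intensities are per particle in units of (contrast x volume)^2; mixtures
combine components as I(s) = sum_k v_k I_k(s) / V_k with volume fractions
v_k (sum v_k = 1), optionally multiplied by a hard-sphere structure
factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special

from .exceptions import DataError, FitError
from .sas_io import Curve

__all__ = [
    "ComponentModel",
    "BilayerModel",
    "MixtureModel",
    "form_factor",
    "polydisperse",
    "bilayer_intensity",
    "percus_yevick_sf",
    "mixture_intensity",
    "fit_mixture",
    "batch_fit",
]

_KINDS = ("sphere", "ellipsoid_of_revolution", "cylinder",
          "core_shell_sphere", "bilayer_vesicle")

#: Gauss-Legendre nodes for orientational averages.
N_ORIENT_NODES = 64
#: Quadrature nodes for polydispersity averages.
N_SIZE_NODES = 51
#: Size distributions are integrated over +/- this many relative widths.
SIZE_SPAN = 4.0


@dataclass
class BilayerModel:
    """Symmetric lipid bilayer as three Gaussians in the electron-density profile.

    Two headgroup Gaussians of amplitude ``rho_H`` and width ``sigma_H`` sit
    at ``+/- z_H`` from the bilayer centre; one methyl-trough Gaussian of
    (typically negative) amplitude ``rho_C`` and width ``sigma_C`` sits at
    the centre. Multilamellar organisation is described by ``N_lam``
    stacked bilayers with repeat ``d_lam`` and Gaussian stacking disorder
    ``sigma_d``; ``f_diffuse`` is the unilamellar (purely diffuse) fraction.
    """

    z_H: float
    sigma_H: float
    rho_H: float
    sigma_C: float
    rho_C: float
    N_lam: int = 1
    d_lam: float = 6.0
    sigma_d: float = 0.0
    f_diffuse: float = 1.0
    lorentz: bool = True

    def validate(self) -> None:
        if min(self.z_H, self.sigma_H, self.sigma_C, self.d_lam) <= 0:
            raise DataError("z_H, sigma_H, sigma_C and d_lam must be positive")
        if self.N_lam < 1 or int(self.N_lam) != self.N_lam:
            raise DataError("N_lam must be an integer >= 1")
        if not 0.0 <= self.f_diffuse <= 1.0:
            raise DataError("f_diffuse must lie in [0, 1]")
        if self.sigma_d < 0:
            raise DataError("sigma_d must be non-negative")


@dataclass
class ComponentModel:
    """One scattering component: a geometric body plus polydispersity and contrast.

    ``params`` is kind-specific:
      sphere                  R
      ellipsoid_of_revolution a, epsilon   (semi-axes a, a, epsilon*a)
      cylinder                R, L
      core_shell_sphere       R_core, R_total, drho_core, drho_shell
      bilayer_vesicle         bilayer (a BilayerModel)
    Polydispersity applies to the leading dimension (R, a, R for cylinder,
    R_total for core-shell with the core scaled proportionally).
    """

    kind: str
    params: dict
    polydispersity: float = 0.0          # relative width dR/R
    distribution: str = "gaussian"       # or "schulz"
    contrast: float = 1.0

    def validate(self) -> None:
        if self.kind not in _KINDS:
            raise DataError(f"unknown component kind {self.kind!r}")
        if not 0.0 <= self.polydispersity < 0.7:
            raise DataError("relative polydispersity must lie in [0, 0.7)")
        if self.distribution not in ("gaussian", "schulz"):
            raise DataError(f"unknown size distribution {self.distribution!r}")
        p = self.params
        if self.kind == "sphere":
            if p["R"] <= 0:
                raise DataError("sphere radius must be positive")
        elif self.kind == "ellipsoid_of_revolution":
            if p["a"] <= 0 or p["epsilon"] <= 0:
                raise DataError("ellipsoid semi-axis and axial ratio must be positive")
        elif self.kind == "cylinder":
            if p["R"] <= 0 or p["L"] <= 0:
                raise DataError("cylinder radius and length must be positive")
        elif self.kind == "core_shell_sphere":
            if p["R_core"] <= 0 or p["R_total"] <= p["R_core"]:
                raise DataError("need 0 < R_core < R_total")
        elif self.kind == "bilayer_vesicle":
            p["bilayer"].validate()

    def volume(self) -> float:
        """Particle volume of the mean-size body (1 for bilayers)."""
        p = self.params
        if self.kind == "sphere":
            return 4.0 / 3.0 * math.pi * p["R"] ** 3
        if self.kind == "ellipsoid_of_revolution":
            return 4.0 / 3.0 * math.pi * p["epsilon"] * p["a"] ** 3
        if self.kind == "cylinder":
            return math.pi * p["R"] ** 2 * p["L"]
        if self.kind == "core_shell_sphere":
            return 4.0 / 3.0 * math.pi * p["R_total"] ** 3
        return 1.0


@dataclass
class MixtureModel:
    """Components with volume fractions and an optional hard-sphere structure factor."""

    components: list
    volume_fractions: np.ndarray
    structure_factor: Optional[dict] = None   # {"kind": "hard_sphere", "R_hs":, "eta_hs":}

    def __post_init__(self):
        v = np.asarray(self.volume_fractions, dtype=float)
        if len(v) != len(self.components) or np.any(v < 0) or v.sum() <= 0:
            raise DataError("volume fractions must be non-negative, one per component")
        self.volume_fractions = v / v.sum()


def _sphere_amp(x: np.ndarray) -> np.ndarray:
    """Phi(x) = 3 (sin x - x cos x) / x^3, the normalised sphere amplitude."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    small = np.abs(x) < 1e-4
    xs = x[~small]
    out[~small] = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs ** 3
    # series: 1 - x^2/10 + x^4/280
    xt = x[small]
    out[small] = 1.0 - xt ** 2 / 10.0 + xt ** 4 / 280.0
    return out


def _sinc(x: np.ndarray) -> np.ndarray:
    """sin(x)/x with the limit 1 at x = 0."""
    return np.sinc(np.asarray(x) / np.pi)


def _j1_over_x(x: np.ndarray) -> np.ndarray:
    """2 J1(x)/x with the limit 1 at x = 0."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-8
    out[nz] = 2.0 * special.j1(x[nz]) / x[nz]
    return out


def _orient_nodes(n: int = N_ORIENT_NODES):
    # Average over alpha in [0, pi/2] with weight sin(alpha) d(alpha);
    # substitute mu = cos(alpha) so the weight becomes uniform on [0, 1].
    x, w = np.polynomial.legendre.leggauss(n)
    mu = 0.5 * (x + 1.0)
    return mu, 0.5 * w


def form_factor(component: ComponentModel, s) -> np.ndarray:
    """Monodisperse orientation-averaged intensity I(s) of one component.

    Units are (contrast x volume)^2, so I(0) = (drho V)^2 for compact
    bodies. Anisotropic bodies are averaged over orientation with
    fixed-order Gauss-Legendre quadrature.
    """
    component.validate()
    s = np.asarray(s, dtype=float)
    p = component.params
    drho = component.contrast

    if component.kind == "sphere":
        V = component.volume()
        return (drho * V) ** 2 * _sphere_amp(s * p["R"]) ** 2

    if component.kind == "core_shell_sphere":
        Rc, Rt = p["R_core"], p["R_total"]
        dc, ds_ = p["drho_core"], p["drho_shell"]
        Vc = 4.0 / 3.0 * math.pi * Rc ** 3
        Vt = 4.0 / 3.0 * math.pi * Rt ** 3
        amp = dc * Vc * _sphere_amp(s * Rc) + ds_ * (Vt * _sphere_amp(s * Rt)
                                                     - Vc * _sphere_amp(s * Rc))
        return amp ** 2

    if component.kind == "ellipsoid_of_revolution":
        a, eps = p["a"], p["epsilon"]
        V = component.volume()
        mu, w = _orient_nodes()
        # effective radius at orientation mu = cos(alpha)
        r = a * np.sqrt(1.0 + (eps ** 2 - 1.0) * mu ** 2)
        amp2 = _sphere_amp(np.outer(s, r)) ** 2
        return (drho * V) ** 2 * amp2 @ w

    if component.kind == "cylinder":
        R, L = p["R"], p["L"]
        V = component.volume()
        mu, w = _orient_nodes()
        sin_a = np.sqrt(1.0 - mu ** 2)
        amp = (_j1_over_x(np.outer(s, R * sin_a))
               * _sinc(np.outer(s, L * mu / 2.0)))
        return (drho * V) ** 2 * (amp ** 2) @ w

    if component.kind == "bilayer_vesicle":
        return bilayer_intensity(p["bilayer"], s)

    raise DataError(f"unknown component kind {component.kind!r}")


def _scaled_component(component: ComponentModel, factor: float) -> ComponentModel:
    """Scale the leading dimension (and proportional lengths) by ``factor``."""
    p = dict(component.params)
    if component.kind == "sphere":
        p["R"] = p["R"] * factor
    elif component.kind == "ellipsoid_of_revolution":
        p["a"] = p["a"] * factor
    elif component.kind == "cylinder":
        p["R"] = p["R"] * factor
    elif component.kind == "core_shell_sphere":
        p["R_core"] = p["R_core"] * factor
        p["R_total"] = p["R_total"] * factor
    return replace(component, params=p, polydispersity=0.0)


def _size_pdf(distribution: str, rel: np.ndarray, width: float) -> np.ndarray:
    """Size distribution density on the relative size axis x = R/R_mean."""
    if distribution == "gaussian":
        return np.exp(-0.5 * ((rel - 1.0) / width) ** 2)
    # Schulz (gamma) with mean 1 and relative width ``width``: z = 1/width^2 - 1
    z = 1.0 / width ** 2 - 1.0
    return rel ** z * np.exp(-(z + 1.0) * rel)


def polydisperse(component: ComponentModel, s) -> np.ndarray:
    """Number-averaged intensity over the component's size distribution.

    Gaussian distributions are truncated at zero size and integrated over
    +/- ``SIZE_SPAN`` relative widths with ``N_SIZE_NODES`` Gauss-Legendre
    nodes; Schulz uses the same quadrature against the gamma density.
    Zero width returns the monodisperse form factor exactly.
    """
    component.validate()
    s = np.asarray(s, dtype=float)
    width = component.polydispersity
    if width == 0.0 or component.kind == "bilayer_vesicle":
        return form_factor(component, s)

    lo = max(1.0 - SIZE_SPAN * width, 1e-6)
    hi = 1.0 + (SIZE_SPAN if component.distribution == "gaussian" else 1.5 * SIZE_SPAN) * width
    x, w = np.polynomial.legendre.leggauss(N_SIZE_NODES)
    rel = 0.5 * (hi - lo) * (x + 1.0) + lo
    wq = 0.5 * (hi - lo) * w
    pdf = _size_pdf(component.distribution, rel, width) * wq
    pdf /= pdf.sum()

    out = np.zeros_like(s)
    for f, pw in zip(rel, pdf):
        out += pw * form_factor(_scaled_component(component, f), s)
    return out


def _bilayer_amplitude(model: BilayerModel, s: np.ndarray) -> np.ndarray:
    """F(s) of the three-Gaussian electron-density profile."""
    return math.sqrt(2.0 * math.pi) * (
        2.0 * model.sigma_H * model.rho_H * np.cos(s * model.z_H)
        * np.exp(-model.sigma_H ** 2 * s ** 2 / 2.0)
        + model.sigma_C * model.rho_C * np.exp(-model.sigma_C ** 2 * s ** 2 / 2.0)
    )


def paracrystal_sf(s, N: int, d: float, sigma_d: float = 0.0) -> np.ndarray:
    """Paracrystalline stacking factor for N lamellae with repeat d.

    S(s) = N + 2 sum_{j=1}^{N-1} (N-j) cos(j s d) exp(-j s^2 sigma_d^2 / 2).
    At a Bragg position s = 2 pi h / d with sigma_d = 0 this equals N^2;
    N = 1 gives S identically 1.
    """
    s = np.asarray(s, dtype=float)
    N = int(N)
    out = np.full_like(s, float(N))
    for j in range(1, N):
        out += 2.0 * (N - j) * np.cos(j * s * d) * np.exp(-j * s ** 2 * sigma_d ** 2 / 2.0)
    return out


def bilayer_intensity(model: BilayerModel, s) -> np.ndarray:
    """Scattering of a (multi)lamellar bilayer system.

    The diffuse (unilamellar) part is F(s)^2 weighted by a 1/s^2 Lorentz
    factor for randomly oriented stacks; the lamellar part multiplies it by
    the paracrystalline stacking factor. ``f_diffuse`` mixes the two. At
    s = 0 the Lorentz factor is skipped (analytic F^2 limit) to keep the
    value finite; set ``lorentz=False`` to disable the factor everywhere.
    """
    model.validate()
    s = np.asarray(s, dtype=float)
    F2 = _bilayer_amplitude(model, s) ** 2
    S = paracrystal_sf(s, model.N_lam, model.d_lam, model.sigma_d)
    S = S / model.N_lam  # per-bilayer normalisation so N_lam=1 reduces to diffuse
    base = model.f_diffuse * F2 + (1.0 - model.f_diffuse) * F2 * S
    if not model.lorentz:
        return base
    out = np.empty_like(base)
    nz = s > 0
    out[nz] = base[nz] / s[nz] ** 2
    out[~nz] = base[~nz]
    return out


def percus_yevick_sf(s, R_hs: float, eta: float) -> np.ndarray:
    """Analytic Percus-Yevick structure factor of hard spheres.

    ``R_hs`` is the hard-sphere interaction radius, ``eta`` the volume
    fraction. ``eta = 0`` gives S identically 1 (dilute limit).
    """
    s = np.asarray(s, dtype=float)
    if eta < 0 or eta >= 0.74:
        raise DataError("hard-sphere volume fraction must lie in [0, 0.74)")
    if eta == 0.0:
        return np.ones_like(s)
    a = (1.0 + 2.0 * eta) ** 2 / (1.0 - eta) ** 4
    b = -6.0 * eta * (1.0 + eta / 2.0) ** 2 / (1.0 - eta) ** 4
    g = eta * a / 2.0
    A = 2.0 * s * R_hs
    out = np.empty_like(A)
    small = A < 1e-4
    As = A[~small]
    sinA, cosA = np.sin(As), np.cos(As)
    G = (a / As ** 2 * (sinA - As * cosA)
         + b / As ** 3 * (2.0 * As * sinA + (2.0 - As ** 2) * cosA - 2.0)
         + g / As ** 5 * (-As ** 4 * cosA
                          + 4.0 * ((3.0 * As ** 2 - 6.0) * cosA
                                   + (As ** 3 - 6.0 * As) * sinA + 6.0)))
    out[~small] = 1.0 / (1.0 + 24.0 * eta * G / As)
    out[small] = (1.0 - eta) ** 4 / (1.0 + 2.0 * eta) ** 2
    return out


def mixture_intensity(model: MixtureModel, s) -> np.ndarray:
    """Total intensity of the mixture.

    I(s) = sum_k v_k I_k(s) / V_k (per-particle intensities divided by the
    particle volume gives volume-fraction weighting), multiplied by the
    hard-sphere Percus-Yevick structure factor when configured.
    """
    s = np.asarray(s, dtype=float)
    out = np.zeros_like(s)
    for comp, v in zip(model.components, model.volume_fractions):
        out += v * polydisperse(comp, s) / comp.volume()
    sf = model.structure_factor
    if sf is not None and sf.get("kind", "none") != "none":
        out = out * percus_yevick_sf(s, sf["R_hs"], sf["eta_hs"])
    return out


# ---------------------------------------------------------------------------
# fitting

_FITTABLE = {
    "sphere": ["R"],
    "ellipsoid_of_revolution": ["a", "epsilon"],
    "cylinder": ["R", "L"],
    "core_shell_sphere": ["R_core", "R_total", "drho_core", "drho_shell"],
}


def _pack(model: MixtureModel, free: dict):
    """Flatten the free parameters into a vector; volume fractions go in as
    softmax logits so the simplex constraint holds by construction."""
    theta, names = [], []
    for ci, comp in enumerate(model.components):
        for pname in free.get(ci, []):
            theta.append(comp.params[pname])
            names.append((ci, pname))
    if free.get("volume_fractions", False) and len(model.components) > 1:
        v = np.clip(model.volume_fractions, 1e-12, None)
        logits = np.log(v)
        logits -= logits[-1]
        for li in range(len(v) - 1):
            theta.append(logits[li])
            names.append(("vf", li))
    return np.array(theta, dtype=float), names


def _unpack(theta, names, model: MixtureModel) -> MixtureModel:
    comps = [replace(c, params=dict(c.params)) for c in model.components]
    vf = model.volume_fractions.copy()
    logits = np.zeros(len(comps))
    any_vf = False
    for val, key in zip(theta, names):
        if key[0] == "vf":
            logits[key[1]] = val
            any_vf = True
        else:
            ci, pname = key
            comps[ci].params[pname] = val
    if any_vf:
        ex = np.exp(logits - logits.max())
        vf = ex / ex.sum()
    return MixtureModel(comps, vf, structure_factor=model.structure_factor)


def _analytic_scale(I_model, I_data, w):
    denom = np.sum(w * I_model ** 2)
    if denom <= 0:
        return 1.0
    return float(np.sum(w * I_model * I_data) / denom)


#: Deterministic multi-start factors applied to free geometric parameters.
START_FACTORS = (1.0, 0.85, 1.18)
_GEOMETRIC = {"R", "a", "L", "R_core", "R_total", "epsilon"}


def fit_mixture(curve: Curve, model: MixtureModel, free: dict,
                max_nfev: int = 2000, multi_start: bool = True):
    """Weighted least-squares fit of a mixture model to a measured curve.

    ``free`` maps component index -> list of parameter names to refine and
    may contain ``"volume_fractions": True``. The overall intensity scale
    is solved analytically at every step, and volume fractions are
    optimised through a softmax reparameterisation so they stay on the
    simplex.

    Because oscillatory form factors make the cost surface multimodal in
    the particle dimensions, the optimiser is restarted from a small
    deterministic grid of rescaled geometric initials (``START_FACTORS``
    per free length parameter, up to three such parameters) and the best
    final cost wins; pass ``multi_start=False`` to fit from the given
    initials only (e.g. when chaining along a slowly varying series).
    Returns ``(fitted_model, scale, chi2_reduced)``.
    """
    for ci, names in free.items():
        if ci == "volume_fractions":
            continue
        kind = model.components[ci].kind
        for nm in names:
            if nm not in _FITTABLE.get(kind, []):
                raise DataError(f"parameter {nm!r} not fittable for kind {kind!r}")

    use = curve.has_sigma
    w = np.where(use, 1.0 / np.where(use, curve.sigma, 1.0) ** 2, 0.0)
    if not np.any(w > 0):
        w = np.ones_like(curve.I)
    theta0, names = _pack(model, free)

    n_free = len(theta0) + 1  # + analytic scale
    if n_free >= len(curve):
        raise DataError("more free parameters than data points")

    def residuals(theta):
        m = _unpack(theta, names, model)
        try:
            I_m = mixture_intensity(m, curve.s)
        except DataError:
            return np.full(len(curve), 1e8)
        scale = _analytic_scale(I_m, curve.I, w)
        return np.sqrt(w) * (scale * I_m - curve.I)

    if len(theta0) == 0:
        I_m = mixture_intensity(model, curve.s)
        scale = _analytic_scale(I_m, curve.I, w)
        r = np.sqrt(w) * (scale * I_m - curve.I)
        dof = max(np.count_nonzero(w) - 1, 1)
        return model, scale, float(np.sum(r ** 2) / dof)

    geom = [j for j, key in enumerate(names)
            if key[0] != "vf" and key[1] in _GEOMETRIC][:3]
    starts = [theta0]
    if multi_start and geom:
        import itertools
        for combo in itertools.product(START_FACTORS, repeat=len(geom)):
            if all(f == 1.0 for f in combo):
                continue
            t = theta0.copy()
            for j, f in zip(geom, combo):
                t[j] *= f
            starts.append(t)

    sol = None
    for t in starts:
        cand = optimize.least_squares(residuals, t, max_nfev=max_nfev)
        if sol is None or (cand.success and cand.cost < sol.cost):
            sol = cand if (cand.success or sol is None) else sol
    if not sol.success:
        raise FitError("mixture fit did not converge", last_iterate=sol.x)
    fitted = _unpack(sol.x, names, model)
    I_m = mixture_intensity(fitted, curve.s)
    scale = _analytic_scale(I_m, curve.I, w)
    dof = max(np.count_nonzero(w) - n_free, 1)
    chi2 = float(np.sum(residuals(sol.x) ** 2) / dof)
    return fitted, scale, chi2


def batch_fit(curves: Sequence[Curve], model: MixtureModel, free: dict,
              chain: bool = True):
    """Fit a series of curves independently or chained.

    In chain mode each fit starts from the previous frame's solution,
    which tracks slowly varying series; otherwise every fit starts from
    the shared initial model. Per-curve failures are returned in place as
    the raised exception rather than aborting the batch. Results are in
    input order regardless of any internal parallelism.
    """
    if not curves:
        raise DataError("batch_fit needs at least one curve")
    results = []
    current = model
    for idx, c in enumerate(curves):
        try:
            # chained fits start close to the optimum; skip the multi-start
            fitted, scale, chi2 = fit_mixture(
                c, current, free, multi_start=(idx == 0 or not chain))
            results.append((fitted, scale, chi2))
            if chain:
                current = fitted
        except (DataError, FitError) as exc:
            results.append(exc)
    return results
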