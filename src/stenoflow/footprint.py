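"""Platelet stress-accumulation analysis: the thrombogenic footprint.

For every platelet-surrogate trajectory the instantaneous viscous shear
stress tensor is formed from the interpolated velocity gradient,

    tau_ij = mu (du_i/dx_j + du_j/dx_i),

collapsed to the scalar stress metric (a von-Mises-type invariant scaled
by 1/sqrt(3), so that pure shear gives sigma = tau_12 exactly)

    sigma = sqrt( (1/3) [ tau_11^2 + tau_22^2 + tau_33^2
                          - tau_11 tau_22 - tau_22 tau_33 - tau_11 tau_33
                          + 3 (tau_12^2 + tau_23^2 + tau_13^2) ] ),

and integrated along the trajectory into the stress accumulation

    SA = integral_0^T sigma dt  ~=  sum_k sigma_k dt        [Pa s].

Endpoint SA values over a seeded population form the thrombogenic
footprint: a log-scale probability density, an activation fraction under
Hellum's 3.5 Pa s threshold (strict inequality), a bulk/tail
decomposition about that threshold, and bootstrap resampling across
population sizes to verify the fraction is population-size independent.

2D velocity gradients are embedded in 3D with zero out-of-plane
components before the invariant is taken.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import DomainError, StenoflowError

#: Hellum's platelet activation threshold on stress accumulation, Pa s.
HELLUM_THRESHOLD_PA_S = 3.5


@dataclass(frozen=True)
class ActivationCriterion:
    """Platelet activation rule: SA strictly above ``threshold`` activates."""

    threshold: float = HELLUM_THRESHOLD_PA_S

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise DomainError("activation threshold must be positive")


# ---------------------------------------------------------------------------
# pointwise stress operations


def shear_stress_tensor(velocity_gradient: np.ndarray,
                        viscosity: float) -> np.ndarray:
    """Viscous shear stress tensor tau_ij = mu (G_ij + G_ji), in Pa.

    ``velocity_gradient`` G_ij = du_i/dx_j may be (..., 2, 2) or
    (..., 3, 3); 2D input is embedded in 3D with zero out-of-plane
    components. The result is symmetric by construction, shape (..., 3, 3).
    """
    G = np.asarray(velocity_gradient, dtype=float)
    if not np.all(np.isfinite(G)):
        bad = np.argwhere(~np.isfinite(G))[0]
        raise StenoflowError(f"non-finite velocity gradient at index {tuple(bad)}")
    d = G.shape[-1]
    if G.shape[-2:] not in ((2, 2), (3, 3)):
        raise DomainError("velocity gradient must be (..., 2, 2) or (..., 3, 3)")
    if d == 2:
        G3 = np.zeros(G.shape[:-2] + (3, 3))
        G3[..., :2, :2] = G
        G = G3
    return viscosity * (G + np.swapaxes(G, -1, -2))


def scalar_stress(tau: np.ndarray, symmetry_tol: float = 1e-8) -> np.ndarray:
    """Scalar stress metric sigma from the stress tensor, in Pa.

    Accepts (..., 3, 3) symmetric tensors (2D tensors are embedded with
    zero out-of-plane components). Identities: hydrostatic tensors give
    0, pure shear tau_12 = t gives t, uniaxial tau_11 = t gives t/sqrt(3).
    """
    t = np.asarray(tau, dtype=float)
    if t.shape[-2:] == (2, 2):
        t3 = np.zeros(t.shape[:-2] + (3, 3))
        t3[..., :2, :2] = t
        t = t3
    if t.shape[-2:] != (3, 3):
        raise DomainError("stress tensor must be (..., 3, 3)")
    asym = np.abs(t - np.swapaxes(t, -1, -2)).max()
    scale = max(float(np.abs(t).max()), 1.0)
    if asym > symmetry_tol * scale:
        raise DomainError(f"stress tensor asymmetric beyond tolerance ({asym:.3e})")
    t11, t22, t33 = t[..., 0, 0], t[..., 1, 1], t[..., 2, 2]
    t12, t23, t13 = t[..., 0, 1], t[..., 1, 2], t[..., 0, 2]
    s2 = (t11**2 + t22**2 + t33**2
          - t11 * t22 - t22 * t33 - t11 * t33
          + 3.0 * (t12**2 + t23**2 + t13**2)) / 3.0
    return np.sqrt(np.maximum(s2, 0.0))


def stress_accumulation(trajectory, rule: str = "left") -> float:
    """Stress accumulation SA = sum_k sigma_k dt_k along a trajectory, Pa s.

    ``trajectory`` must expose ``scalar_stress`` (per-sample sigma, Pa)
    and ``times`` (s). The default left-Riemann rule matches the discrete
    sum sigma * dt; ``rule="trapezoid"`` is available. Non-uniform
    sampling is handled with per-interval dt. SA is additive over
    concatenated trajectory segments.
    """
    sigma = np.asarray(trajectory.scalar_stress, dtype=float)
    t = np.asarray(trajectory.times, dtype=float)
    if sigma.size == 0:
        raise DomainError("trajectory has no samples")
    if sigma.size == 1:
        return 0.0
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise DomainError("trajectory times must be strictly increasing")
    if rule == "left":
        return float(np.sum(sigma[:-1] * dt))
    if rule == "trapezoid":
        return float(np.trapezoid(sigma, t))
    raise DomainError(f"unknown quadrature rule {rule!r}")


# ---------------------------------------------------------------------------
# population statistics


@dataclass
class SAPdf:
    """Probability density of endpoint SA values.

    ``density`` is per unit SA over ``bin_edges`` (log- or linear-spaced);
    the continuous part integrates to 1 - zero_atom_mass, the explicit
    zero atom holding the SA = 0 particles that log bins cannot represent.
    """

    bin_edges: np.ndarray
    density: np.ndarray
    bin_scale: str
    zero_atom_mass: float = 0.0
    degenerate: bool = False

    @property
    def bin_centers(self) -> np.ndarray:
        e = self.bin_edges
        if self.bin_scale == "log":
            return np.sqrt(e[:-1] * e[1:])
        return 0.5 * (e[:-1] + e[1:])

    @property
    def mode(self) -> float:
        """Bulk mode location: centre of the highest-density bin."""
        return float(self.bin_centers[int(np.argmax(self.density))])

    def integral(self) -> float:
        return float(np.sum(self.density * np.diff(self.bin_edges)))


def build_sa_pdf(sa_values: Sequence[float], n_bins: int = 64,
                 bin_scale: str = "log") -> SAPdf:
    """Histogram-estimate the SA probability density.

    Log-scale binning (the reporting convention for SA footprints) spans
    [min positive SA / 2, 2 max SA]; SA = 0 particles go to an explicit
    zero-mass atom reported separately. All-identical values produce a
    degenerate single-bin density, flagged.
    """
    sa = np.asarray(sa_values, dtype=float)
    if sa.size < 2:
        raise DomainError("need at least two SA values for a PDF")
    if np.any(sa < 0):
        raise DomainError("SA values must be non-negative")
    if bin_scale not in ("log", "linear"):
        raise DomainError(f"unknown bin_scale {bin_scale!r}")
    zero_mass = 0.0
    pos = sa
    if bin_scale == "log":
        zero_mass = float(np.mean(sa == 0.0))
        pos = sa[sa > 0.0]
        if pos.size == 0:
            raise DomainError("log-scale PDF needs at least one positive SA")
    lo, hi = pos.min(), pos.max()
    if lo == hi:  # degenerate: all identical
        width = max(abs(lo), 1.0) * 1e-6
        edges = np.array([lo - width / 2, lo + width / 2])
        density = np.array([(1.0 - zero_mass) / width])
        return SAPdf(edges, density, bin_scale, zero_mass, degenerate=True)
    if bin_scale == "log":
        edges = np.geomspace(lo / 2.0, hi * 2.0, n_bins + 1)
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    counts, edges = np.histogram(pos, bins=edges)
    density = counts / sa.size / np.diff(edges)
    return SAPdf(edges, density, bin_scale, zero_mass)


def activation_fraction(sa_values: Sequence[float],
                        criterion: ActivationCriterion = ActivationCriterion(),
                        ) -> float:
    """Fraction of particles with SA strictly above the threshold."""
    sa = np.asarray(sa_values, dtype=float)
    if sa.size == 0:
        raise DomainError("activation fraction of an empty population is undefined")
    return float(np.mean(sa > criterion.threshold))


@dataclass
class BootstrapSummary:
    """Resampled activation fractions across population sizes."""

    resample_sizes: list
    n_replicates: int
    fraction_mean: dict          # size -> mean resampled fraction
    fraction_ci: dict            # size -> (lo, hi) percentile 95% CI
    full_population_fraction: float
    compatible: bool             # full fraction inside every size's CI


def bootstrap_population(
    sa_values: Sequence[float],
    resample_sizes: Sequence[int] = (1000, 2500, 5000, 10000),
    n_replicates: int = 1000,
    rng_seed: int = 0,
    criterion: ActivationCriterion = ActivationCriterion(),
) -> BootstrapSummary:
    """Bootstrap the activation fraction across population sizes.

    For each resample size, ``n_replicates`` with-replacement resamples
    give the mean activation fraction and its percentile 95% CI; the
    population-size-independence verdict is that the full-population
    fraction lies inside every size's CI.
    """
    sa = np.asarray(sa_values, dtype=float)
    if sa.size == 0:
        raise DomainError("cannot bootstrap an empty population")
    if any(s <= 0 for s in resample_sizes):
        raise DomainError("resample sizes must be positive")
    if n_replicates < 100:
        warnings.warn("fewer than 100 bootstrap replicates gives unreliable CIs",
                      stacklevel=2)
    rng = np.random.default_rng(rng_seed)
    active = sa > criterion.threshold
    full = float(np.mean(active))
    means, cis = {}, {}
    compatible = True
    for size in resample_sizes:
        idx = rng.integers(0, sa.size, size=(n_replicates, int(size)))
        fracs = active[idx].mean(axis=1)
        lo, hi = np.percentile(fracs, [2.5, 97.5])
        means[int(size)] = float(fracs.mean())
        cis[int(size)] = (float(lo), float(hi))
        if not (lo <= full <= hi):
            compatible = False
    return BootstrapSummary(
        resample_sizes=[int(s) for s in resample_sizes],
        n_replicates=int(n_replicates),
        fraction_mean=means, fraction_ci=cis,
        full_population_fraction=full, compatible=compatible)


@dataclass
class RegionSummary:
    """Mass, mode and mean of one region of the SA distribution."""

    mass: float
    mode: Optional[float]
    mean: Optional[float]


def split_bulk_tail(pdf: SAPdf, sa_values: Sequence[float],
                    criterion: ActivationCriterion = ActivationCriterion(),
                    ) -> dict:
    """Split the SA population into bulk (SA <= threshold, the main
    mode) and tail (SA > threshold, elevated activation potential).

    Returns ``{"bulk": RegionSummary, "tail": RegionSummary}``; bulk mass
    + tail mass + the PDF's zero-atom mass equals 1 exactly. An empty
    tail yields a zero-mass tail summary, not an error.
    """
    if pdf.degenerate:
        raise DomainError("bulk/tail split needs a non-degenerate PDF")
    sa = np.asarray(sa_values, dtype=float)
    thr = criterion.threshold
    pos = sa[sa > 0] if pdf.bin_scale == "log" else sa
    tail_v = pos[pos > thr]
    bulk_v = pos[pos <= thr]
    centers = pdf.bin_centers

    def region(values, sel) -> RegionSummary:
        mass = values.size / sa.size
        if values.size == 0:
            return RegionSummary(mass=0.0, mode=None, mean=None)
        d = np.where(sel, pdf.density, -np.inf)
        mode = float(centers[int(np.argmax(d))]) if np.any(sel) else None
        return RegionSummary(mass=float(mass), mode=mode,
                             mean=float(values.mean()))

    return {
        "bulk": region(bulk_v, centers <= thr),
        "tail": region(tail_v, centers > thr),
    }


@dataclass
class SAPopulation:
    """Endpoint SA values of a seeded population with their statistics."""

    sa_values: np.ndarray
    criterion: ActivationCriterion
    pdf: SAPdf
    activation_fraction: float
    bootstrap: Optional[BootstrapSummary] = None
    regions: Optional[dict] = None

    @property
    def n(self) -> int:
        return int(self.sa_values.size)


def analyze_population(
    sa_values: Sequence[float],
    criterion: ActivationCriterion = ActivationCriterion(),
    n_bins: int = 64,
    bin_scale: str = "log",
    bootstrap_sizes: Optional[Sequence[int]] = (1000, 2500, 5000, 10000),
    n_replicates: int = 1000,
    rng_seed: int = 0,
) -> SAPopulation:
    """Full footprint statistics for one endpoint-SA population."""
    sa = np.asarray(sa_values, dtype=float)
    pdf = build_sa_pdf(sa, n_bins=n_bins, bin_scale=bin_scale)
    frac = activation_fraction(sa, criterion)
    boot = None
    if bootstrap_sizes:
        sizes = [s for s in bootstrap_sizes if s <= sa.size] or [sa.size]
        boot = bootstrap_population(sa, sizes, n_replicates, rng_seed, criterion)
    regions = None if pdf.degenerate else split_bulk_tail(pdf, sa, criterion)
    return SAPopulation(sa_values=sa, criterion=criterion, pdf=pdf,
                        activation_fraction=frac, bootstrap=boot,
                        regions=regions)
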