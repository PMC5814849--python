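"""Contact-probability mechanics of the leg-placing reaction.

The stepping rate of the walker is limited by forming the *first* base pair
between the free leg and the fuel held on the next foothold. In this coarse
model the two halves of the system are independent tethered arms:

* the *bound arm*: foothold stem, foothold-fuel duplex, fuel-leg duplex,
  inter-leg hinge and the free leg, anchored at the origami attachment of
  the rear foothold, reactive end at the free leg's terminus;
* the *fuel arm*: foothold stem, foothold-fuel duplex and the single-
  stranded fuel overhang, anchored at the front foothold, reactive end at
  the overhang terminus.

Both arms are sampled as freely-jointed chains of rigid links over a
hard-wall track (flat plane or convex cylinder). The probability that the
two reactive ends approach within the capture radius delta is estimated by
the overlap integral

    p(d) ~ (4*pi/3) * delta^3 * integral rho_A(r) rho_B(r) dr,

with each end density estimated by kernel smoothing on a 1-nm grid, plus a
direct pairwise-hit estimator as an internal cross-check. Only barrier
*differences* are physical here: delta_dG(d) = -ln p(d)/p(d_ref), which is
converted into stepping rates relative to an experimentally calibrated
reference step and hence into yield curves via the kinetic competition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .kinetics import DEFAULT_K_FB, KineticParams, yield_from_rates
from .polymer import (
    ChainSample,
    CylinderSurface,
    FlatSurface,
    SamplingFailureError,
    SegmentSpec,
    arm_contour_length,
    arm_link_lengths,
    ds_segment,
    sample_chain,
    ss_segment,
)

__all__ = [
    "DEFAULT_CAPTURE_RADIUS_NM",
    "DEFAULT_REFERENCE_STEP_NM",
    "ORIGAMI_WIDTH_NM",
    "DEFAULT_CYLINDER_RADIUS_NM",
    "WalkerDesign",
    "TrackGeometry",
    "ContactEstimate",
    "HairpinModel",
    "Calibration",
    "YieldPrediction",
    "EndDensity",
    "UndefinedReferenceError",
    "default_walker_design",
    "chord_from_arc",
    "delta_barrier",
    "max_reach",
    "sample_end_density",
    "ContactModel",
    "BlendedContactModel",
    "apply_hairpin",
    "contact_probability",
    "predict_yield_curve",
]

#: Capture radius for the first leg-placing base pair (nm), order of one
#: base-pair bond distance.
DEFAULT_CAPTURE_RADIUS_NM = 1.0
#: Step size at which predicted relative rates are anchored to experiment.
DEFAULT_REFERENCE_STEP_NM = 12.0
#: Width of the rectangular origami short axis (nm).
ORIGAMI_WIDTH_NM = 60.0
#: Cylinder radius whose circumference equals the origami width (nm).
DEFAULT_CYLINDER_RADIUS_NM = ORIGAMI_WIDTH_NM / (2.0 * math.pi)

#: Default KDE bandwidth (nm). Narrow enough that the kernel-smoothing bias
#: of the overlap integral stays below the Monte-Carlo error at the sample
#: sizes used (verified against the unsmoothed pairwise-hit estimator).
DEFAULT_BANDWIDTH_NM = 0.5
#: Gaussian kernel cut-off, in units of the bandwidth. Deliberately long
#: (8 nm at the default bandwidth) so the smoothed densities stay strictly
#: positive all the way to the clipped geometric support, which is what lets
#: the overlap estimator resolve the very rare contacts near the reach limit
#: (hit probabilities << 1e-6).
KDE_TRUNCATE = 16.0


class UndefinedReferenceError(ValueError):
    """Raised when a barrier difference is requested against p_ref = 0."""


@dataclass(frozen=True)
class WalkerDesign:
    """Segment-level description of the two tethered arms.

    ``arm_bound`` runs from the rear-foothold anchor to the free leg
    terminus; ``arm_fuel`` from the front-foothold anchor to the fuel
    overhang terminus. ``capture_radius`` (nm) is the end-to-end distance
    below which the first leg-placing base pair is considered formable.
    """

    arm_bound: tuple[SegmentSpec, ...]
    arm_fuel: tuple[SegmentSpec, ...]
    capture_radius: float = DEFAULT_CAPTURE_RADIUS_NM

    def __post_init__(self) -> None:
        if not self.arm_bound or not self.arm_fuel:
            raise ValueError("both arms must have at least one segment")
        if not self.capture_radius > 0:
            raise ValueError(f"capture_radius must be > 0, got {self.capture_radius!r}")

    @property
    def bound_contour(self) -> float:
        return arm_contour_length(self.arm_bound)

    @property
    def fuel_contour(self) -> float:
        return arm_contour_length(self.arm_fuel)


def default_walker_design(capture_radius: float = DEFAULT_CAPTURE_RADIUS_NM) -> WalkerDesign:
    """Default construct geometry.

    The fuel is held by an 18-bp duplex on the foothold and binds the leg by
    16 bp, so the single-stranded fuel overhang and the free leg domain are
    16 nt each; anchor spacers (2 nt) and the inter-leg hinge (3 nt) are
    short flexible linkers. The rear foothold-fuel-leg duplex complex
    (18 + 16 bp, nicked but coaxially stacked) is one rigid rod: stacked
    nicked duplexes this far below the duplex persistence length behave as
    continuous helices, and treating the nick as a free joint makes the
    activation barrier rise far more steeply over 5-20 nm steps than is
    observed for this walker. All lengths are overridable through the
    config.
    """
    arm_bound = (
        ss_segment(2, name="t2_spacer"),
        ds_segment(34, name="t2_f2_l2_stack"),
        ss_segment(3, name="leg_hinge"),
        ss_segment(16, name="l1_free"),
    )
    arm_fuel = (
        ss_segment(2, name="t1_spacer"),
        ds_segment(18, name="t1_f1_duplex"),
        ss_segment(16, name="f1_overhang"),
    )
    return WalkerDesign(arm_bound=arm_bound, arm_fuel=arm_fuel, capture_radius=capture_radius)


@dataclass(frozen=True)
class TrackGeometry:
    """Flat plane or convex cylinder with two foothold anchors.

    ``separation`` is the anchor separation: a straight in-plane distance on
    the flat track, an arc length around the circumference on the cylinder.
    Arc separations beyond half the circumference are reached the shorter
    way around (wrap-around).
    """

    kind: Literal["flat", "cylinder"]
    separation: float = 0.0
    radius: float | None = None
    walker_side: Literal["convex"] = "convex"

    def __post_init__(self) -> None:
        if self.kind not in ("flat", "cylinder"):
            raise ValueError(f"kind must be 'flat' or 'cylinder', got {self.kind!r}")
        if self.separation < 0:
            raise ValueError(f"separation must be >= 0, got {self.separation!r}")
        if self.kind == "cylinder":
            if self.radius is None or not self.radius > 0:
                raise ValueError("cylinder tracks need a positive radius")

    @property
    def circumference(self) -> float:
        if self.kind != "cylinder":
            raise ValueError("circumference is only defined for cylinder tracks")
        assert self.radius is not None
        return 2.0 * math.pi * self.radius

    def effective_separation(self, separation: float | None = None) -> float:
        """Separation actually used for geometry (shorter way around a tube)."""
        s = self.separation if separation is None else separation
        if self.kind == "flat":
            return s
        c = self.circumference
        s_mod = s % c
        return min(s_mod, c - s_mod)

    def surface(self) -> FlatSurface | CylinderSurface:
        if self.kind == "flat":
            return FlatSurface()
        assert self.radius is not None
        return CylinderSurface(self.radius)


@dataclass(frozen=True)
class ContactEstimate:
    """Contact probability and relative activation barrier at one step size."""

    d: float
    p_contact: float
    dG_rel: float
    stderr: float
    n_samples: int
    seed: int
    method: str = "overlap"
    p_reference: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_contact <= 1.0:
            raise ValueError(f"p_contact must lie in [0, 1], got {self.p_contact!r}")
        if self.stderr < 0:
            raise ValueError(f"stderr must be >= 0, got {self.stderr!r}")
        if (self.p_contact > 0) != math.isfinite(self.dG_rel):
            raise ValueError("dG_rel must be finite exactly when p_contact > 0")


@dataclass(frozen=True)
class HairpinModel:
    """Transient hairpin in the fuel overhang.

    ``dG_hp`` is the folding free energy in k_B*T (negative = folded
    favoured); ``sequestered_units`` is the number of overhang nucleotides
    unavailable while folded. The open-state probability is the two-state
    Boltzmann weight ``1 / (1 + exp(-dG_hp))``.
    """

    dG_hp: float
    sequestered_units: int

    def __post_init__(self) -> None:
        if self.sequestered_units < 0:
            raise ValueError("sequestered_units must be >= 0")

    @property
    def p_open(self) -> float:
        return 1.0 / (1.0 + math.exp(-self.dG_hp))


@dataclass(frozen=True)
class Calibration:
    """Anchor of predicted relative rates to an experimental stepping rate.

    The default ``k_s_ref`` of 3.5 s^-1 is the short-step stepping rate
    implied by the measured 3.5e-5 s^-1 at 35 nm being five orders of
    magnitude below the short-step rates.
    """

    d_ref: float = DEFAULT_REFERENCE_STEP_NM
    k_s_ref: float = 3.5
    k_FB: float = DEFAULT_K_FB

    def __post_init__(self) -> None:
        if not self.k_s_ref > 0:
            raise ValueError("k_s_ref must be > 0")
        if not self.k_FB > 0:
            raise ValueError("k_FB must be > 0")


def chord_from_arc(s: float, radius: float) -> float:
    """Straight-line chord for an arc separation on a cylinder cross-section.

    Uses the shorter way around for arcs beyond half the circumference:
    ``2R sin(min(s mod C, C - s mod C) / 2R)``.
    """
    if s < 0:
        raise ValueError(f"arc length must be >= 0, got {s!r}")
    if not radius > 0:
        raise ValueError(f"radius must be > 0, got {radius!r}")
    c = 2.0 * math.pi * radius
    s_mod = s % c
    s_eff = min(s_mod, c - s_mod)
    return 2.0 * radius * math.sin(s_eff / (2.0 * radius))


def delta_barrier(p_d: float, p_ref: float) -> float:
    """Barrier difference ``-ln(p_d / p_ref)`` in k_B*T; +inf when p_d = 0."""
    if not p_ref > 0:
        raise UndefinedReferenceError("reference contact probability must be > 0")
    if p_d < 0:
        raise ValueError(f"p_d must be >= 0, got {p_d!r}")
    if p_d == 0.0:
        return math.inf
    return -math.log(p_d / p_ref)


def max_reach(design: WalkerDesign, track: TrackGeometry | None = None) -> float:
    """Largest anchor separation at which the reactive ends can meet (nm).

    Both arms fully stretched plus the capture radius. On the flat track
    this is a straight-line separation; on the cylinder it is returned as an
    arc length (arms hugging the convex surface), with wrap-around applied
    by :meth:`TrackGeometry.effective_separation` at evaluation time.
    """
    reach = design.bound_contour + design.fuel_contour + design.capture_radius
    return reach


@dataclass
class EndDensity:
    """Reactive-end sample cloud of one arm with a binned 3-D density."""

    sample: ChainSample
    edges: tuple[np.ndarray, np.ndarray, np.ndarray]
    grid: np.ndarray
    seed: int

    @property
    def points(self) -> np.ndarray:
        return self.sample.ends

    @property
    def acceptance_rate(self) -> float:
        return self.sample.acceptance_rate


def sample_end_density(
    arm: Sequence[SegmentSpec],
    track: TrackGeometry | None,
    anchor: Sequence[float] | None = None,
    n: int = 10_000,
    seed: int = 0,
    grid_spacing: float = 1.0,
    keep_beads: bool = False,
) -> EndDensity:
    """Sample the empirical 3-D density of one arm's reactive end.

    Conformations use uniform random joint orientations with hard-wall
    rejection; deterministic given ``seed``. The returned object carries the
    raw sample cloud, the acceptance rate and a histogram on a
    ``grid_spacing`` grid.
    """
    surface = None if track is None else track.surface()
    if anchor is None:
        anchor = (0.0, 0.0, 0.0) if surface is None else surface.anchor(0.0)
    rng = np.random.default_rng(seed)
    sample = sample_chain(
        arm_link_lengths(arm), n, rng, surface=surface, anchor=anchor, keep_beads=keep_beads
    )
    lo = np.floor(sample.ends.min(axis=0) - grid_spacing)
    hi = np.ceil(sample.ends.max(axis=0) + grid_spacing)
    edges = tuple(np.arange(lo[k], hi[k] + grid_spacing, grid_spacing) for k in range(3))
    grid, _ = np.histogramdd(sample.ends, bins=edges)
    return EndDensity(sample=sample, edges=edges, grid=grid, seed=seed)


def _voxel_centers(edges: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return tuple(0.5 * (e[1:] + e[:-1]) for e in edges)


def _voxel_indices(points: np.ndarray, lo: np.ndarray, spacing: float, shape: tuple[int, ...]) -> tuple:
    idx = np.floor((points - lo) / spacing).astype(np.intp)
    for k in range(3):
        np.clip(idx[:, k], 0, shape[k] - 1, out=idx[:, k])
    return idx[:, 0], idx[:, 1], idx[:, 2]


class ContactModel:
    """Cached two-arm sampler evaluating contact probabilities vs separation.

    The two arms are sampled once at a canonical anchor; separations are
    evaluated by rigid transformation of the fuel-arm cloud (translation
    along the track on the plane, rotation about the axis on the cylinder),
    so one pair of clouds serves an entire step-size grid.
    """

    def __init__(
        self,
        design: WalkerDesign,
        track: TrackGeometry,
        n: int = 100_000,
        seed: int = 0,
        grid_spacing: float = 1.0,
        bandwidth: float = DEFAULT_BANDWIDTH_NM,
        n_boot: int = 64,
    ) -> None:
        if n < 1:
            raise ValueError("n must be >= 1")
        self.design = design
        self.track = track
        self.n = int(n)
        self.seed = int(seed)
        self.grid_spacing = float(grid_spacing)
        self.bandwidth = float(bandwidth)
        self.n_boot = int(n_boot)
        self.surface = track.surface()

        ss_bound, ss_fuel, ss_boot = np.random.SeedSequence(seed).spawn(3)
        anchor = self.surface.anchor(0.0)
        self.bound = sample_chain(
            arm_link_lengths(design.arm_bound), self.n, np.random.default_rng(ss_bound),
            surface=self.surface, anchor=anchor,
        )
        self.fuel = sample_chain(
            arm_link_lengths(design.arm_fuel), self.n, np.random.default_rng(ss_fuel),
            surface=self.surface, anchor=anchor,
        )
        self._boot_rng = np.random.default_rng(ss_boot)
        self.bound_contour = design.bound_contour
        self.fuel_contour = design.fuel_contour

    # -- geometry -----------------------------------------------------------

    def _fuel_cloud_at(self, separation: float) -> tuple[np.ndarray, np.ndarray]:
        """Fuel-arm end cloud and anchor transformed to a given separation."""
        s_eff = self.track.effective_separation(separation)
        if self.track.kind == "flat":
            offset = np.array([s_eff, 0.0, 0.0])
            return self.fuel.ends + offset, self.fuel.anchor + offset
        assert isinstance(self.surface, CylinderSurface)
        pts = self.surface.rotate(self.fuel.ends, s_eff)
        anchor = self.surface.anchor(s_eff)
        return pts, anchor

    # -- estimators ---------------------------------------------------------

    def _overlap_probability(self, separation: float) -> tuple[float, float]:
        pts_a, anchor_a = self.bound.ends, self.bound.anchor
        pts_b, anchor_b = self._fuel_cloud_at(separation)
        spacing = self.grid_spacing
        sigma_vox = self.bandwidth / spacing

        all_min = np.minimum(pts_a.min(axis=0), pts_b.min(axis=0))
        all_max = np.maximum(pts_a.max(axis=0), pts_b.max(axis=0))
        pad = KDE_TRUNCATE * self.bandwidth + spacing
        lo = np.floor(all_min - pad)
        hi = np.ceil(all_max + pad)
        edges = tuple(np.arange(lo[k], hi[k] + spacing, spacing) for k in range(3))
        shape = tuple(len(e) - 1 for e in edges)
        vox_vol = spacing**3
        cx, cy, cz = _voxel_centers(edges)
        gx, gy, gz = np.meshgrid(cx, cy, cz, indexing="ij")
        centers = np.stack([gx, gy, gz], axis=-1)

        # Support masks: hard clip at each arm's exact contour radius plus a
        # lenient one-voxel wall mask (boundary voxels straddle the wall).
        if isinstance(self.surface, CylinderSurface):
            lenient = CylinderSurface(self.surface.radius, tol=spacing)
        else:
            lenient = FlatSurface(tol=spacing)
        surf_ok = lenient.allowed(centers)
        dist_a = np.linalg.norm(centers - anchor_a, axis=-1)
        dist_b = np.linalg.norm(centers - anchor_b, axis=-1)
        mask_a = (dist_a <= self.bound_contour) & surf_ok
        mask_b = (dist_b <= self.fuel_contour) & surf_ok

        # Boundary-corrected kernel densities: dividing the smoothed
        # histogram by the smoothed support indicator renormalizes each
        # kernel by the fraction of its mass inside the allowed region,
        # removing the first-order underestimate next to the wall and the
        # support edge.
        def boundary_kernel(mask: np.ndarray) -> np.ndarray:
            gm = gaussian_filter(mask.astype(float), sigma=sigma_vox, truncate=KDE_TRUNCATE)
            return np.divide(mask.astype(float), gm, out=np.zeros(mask.shape), where=gm > 0)

        kern_a = boundary_kernel(mask_a)
        kern_b = boundary_kernel(mask_b)
        hist_a, _ = np.histogramdd(pts_a, bins=edges)
        hist_b, _ = np.histogramdd(pts_b, bins=edges)
        sm_a = kern_a * gaussian_filter(hist_a, sigma=sigma_vox, truncate=KDE_TRUNCATE)
        sm_b = kern_b * gaussian_filter(hist_b, sigma=sigma_vox, truncate=KDE_TRUNCATE)
        norm_a = sm_a.sum()
        norm_b = sm_b.sum()
        if norm_a <= 0 or norm_b <= 0:
            raise SamplingFailureError("kernel density lost all mass to the support clip")
        dens_a = sm_a / (norm_a * vox_vol)
        dens_b = sm_b / (norm_b * vox_vol)
        overlap = float((dens_a * dens_b).sum() * vox_vol)
        v_delta = (4.0 * math.pi / 3.0) * self.design.capture_radius**3
        p = min(overlap * v_delta, 1.0)
        if overlap <= 0.0:
            return 0.0, 0.0

        # Bootstrap over conformations, one side at a time. The overlap is
        # linear in each arm's histogram, and the Gaussian filter is
        # self-adjoint, so the integral equals a ratio of per-conformation
        # voxel lookups; resampling those is an exact conformation bootstrap.
        se_parts = []
        for pts, kern, dens_other in ((pts_a, kern_a, dens_b), (pts_b, kern_b, dens_a)):
            g = gaussian_filter(kern * dens_other, sigma=sigma_vox, truncate=KDE_TRUNCATE)
            m = gaussian_filter(kern, sigma=sigma_vox, truncate=KDE_TRUNCATE)
            ii = _voxel_indices(pts, lo, spacing, shape)
            g_i = g[ii]
            m_i = m[ii]
            n_pts = pts.shape[0]
            idx = self._boot_rng.integers(0, n_pts, size=(self.n_boot, n_pts))
            num = g_i[idx].mean(axis=1)
            den = m_i[idx].mean(axis=1)
            ratios = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
            se_parts.append(float(np.std(ratios, ddof=1)))
        se = v_delta * math.hypot(*se_parts)
        return p, se

    def _direct_probability(self, separation: float) -> tuple[float, float]:
        pts_a = self.bound.ends
        pts_b, _ = self._fuel_cloud_at(separation)
        delta = self.design.capture_radius
        counts_a = cKDTree(pts_b).query_ball_point(pts_a, delta, return_length=True)
        counts_b = cKDTree(pts_a).query_ball_point(pts_b, delta, return_length=True)
        n_a, n_b = len(pts_a), len(pts_b)
        p = float(counts_a.sum()) / (n_a * n_b)
        if p == 0.0:
            return 0.0, 0.0
        se_parts = []
        for counts, n_other in ((counts_a, n_b), (counts_b, n_a)):
            idx = self._boot_rng.integers(0, len(counts), size=(self.n_boot, len(counts)))
            boots = counts[idx].mean(axis=1) / n_other
            se_parts.append(float(np.std(boots, ddof=1)))
        return p, math.hypot(*se_parts)

    def probability(self, separation: float, method: str = "overlap") -> tuple[float, float]:
        """Contact probability and bootstrap standard error at one separation."""
        if method == "overlap":
            return self._overlap_probability(separation)
        if method == "direct":
            return self._direct_probability(separation)
        raise ValueError(f"unknown method {method!r}; expected 'overlap' or 'direct'")

    def estimate(
        self,
        separation: float,
        reference_separation: float | None = DEFAULT_REFERENCE_STEP_NM,
        method: str = "overlap",
    ) -> ContactEstimate:
        """Full contact estimate with barrier relative to a reference step."""
        p, se = self.probability(separation, method=method)
        if reference_separation is None:
            p_ref = None
            dg = 0.0 if p > 0 else math.inf
        else:
            p_ref, _ = self.probability(reference_separation, method=method)
            dg = delta_barrier(p, p_ref)
        return ContactEstimate(
            d=separation,
            p_contact=p,
            dG_rel=dg,
            stderr=se,
            n_samples=self.n,
            seed=self.seed,
            method=method,
            p_reference=p_ref,
        )


@dataclass(frozen=True)
class EffectiveHairpinDesign:
    """Two-state (open/folded) design mixture produced by a fuel hairpin."""

    design_open: WalkerDesign
    design_folded: WalkerDesign
    p_open: float
    hairpin: HairpinModel


def apply_hairpin(design: WalkerDesign, hairpin: HairpinModel) -> EffectiveHairpinDesign:
    """Two-state effective contact model of a transient fuel hairpin.

    The folded state sequesters ``sequestered_units`` nucleotides of the
    terminal fuel overhang, shortening the fuel arm; contact probabilities
    are the Boltzmann-weighted mixture of open and folded designs.
    """
    overhang = design.arm_fuel[-1]
    if overhang.kind != "single_stranded":
        raise ValueError("the fuel arm must end in a single-stranded overhang to fold a hairpin")
    if hairpin.sequestered_units > overhang.n_units:
        raise ValueError(
            f"sequestered_units ({hairpin.sequestered_units}) exceeds the overhang length "
            f"({overhang.n_units} nt)"
        )
    if hairpin.sequestered_units == overhang.n_units:
        folded_fuel = design.arm_fuel[:-1]
    elif hairpin.sequestered_units == 0:
        folded_fuel = design.arm_fuel
    else:
        folded_fuel = design.arm_fuel[:-1] + (
            replace(overhang, n_units=overhang.n_units - hairpin.sequestered_units),
        )
    folded = WalkerDesign(
        arm_bound=design.arm_bound,
        arm_fuel=folded_fuel,
        capture_radius=design.capture_radius,
    )
    return EffectiveHairpinDesign(
        design_open=design, design_folded=folded, p_open=hairpin.p_open, hairpin=hairpin
    )


class BlendedContactModel:
    """Contact model mixing open and folded fuel-overhang states."""

    def __init__(
        self,
        effective: EffectiveHairpinDesign,
        track: TrackGeometry,
        n: int = 100_000,
        seed: int = 0,
        grid_spacing: float = 1.0,
        bandwidth: float = DEFAULT_BANDWIDTH_NM,
        n_boot: int = 64,
    ) -> None:
        s_open, s_folded = np.random.SeedSequence(seed).spawn(2)
        kwargs = dict(
            track=track, n=n, grid_spacing=grid_spacing, bandwidth=bandwidth, n_boot=n_boot
        )
        self.effective = effective
        self.seed = int(seed)
        self.n = int(n)
        self.design = effective.design_open
        self.track = track
        self.model_open = ContactModel(
            effective.design_open, seed=int(s_open.generate_state(1)[0] % 2**31), **kwargs
        )
        self.model_folded = ContactModel(
            effective.design_folded, seed=int(s_folded.generate_state(1)[0] % 2**31), **kwargs
        )

    def probability(self, separation: float, method: str = "overlap") -> tuple[float, float]:
        w = self.effective.p_open
        p_o, se_o = self.model_open.probability(separation, method=method)
        p_f, se_f = self.model_folded.probability(separation, method=method)
        p = w * p_o + (1.0 - w) * p_f
        se = math.hypot(w * se_o, (1.0 - w) * se_f)
        return p, se

    def estimate(
        self,
        separation: float,
        reference_separation: float | None = DEFAULT_REFERENCE_STEP_NM,
        method: str = "overlap",
    ) -> ContactEstimate:
        p, se = self.probability(separation, method=method)
        if reference_separation is None:
            p_ref = None
            dg = 0.0 if p > 0 else math.inf
        else:
            p_ref, _ = self.probability(reference_separation, method=method)
            dg = delta_barrier(p, p_ref)
        return ContactEstimate(
            d=separation,
            p_contact=p,
            dG_rel=dg,
            stderr=se,
            n_samples=self.n,
            seed=self.seed,
            method=method,
            p_reference=p_ref,
        )


def contact_probability(
    design: WalkerDesign,
    track: TrackGeometry,
    n: int = 100_000,
    seed: int = 0,
    reference_separation: float | None = DEFAULT_REFERENCE_STEP_NM,
    method: str = "overlap",
    model: ContactModel | None = None,
    **model_kwargs,
) -> ContactEstimate:
    """Contact estimate at ``track.separation`` (see :class:`ContactModel`).

    A prebuilt ``model`` may be passed to reuse sampled clouds across calls.
    """
    if model is None:
        model = ContactModel(design, track, n=n, seed=seed, **model_kwargs)
    return model.estimate(track.separation, reference_separation=reference_separation, method=method)


@dataclass
class YieldPrediction:
    """Predicted yield curve with the underlying contact/barrier table."""

    curve: pd.DataFrame
    contacts: pd.DataFrame
    calibration: Calibration
    seed: int
    max_reach: float


def predict_yield_curve(
    design: WalkerDesign,
    track: TrackGeometry,
    d_grid: Sequence[float],
    F1_list: Sequence[float],
    calibration: Calibration | None = None,
    n: int = 100_000,
    seed: int = 0,
    hairpin: HairpinModel | None = None,
    grid_spacing: float = 1.0,
    bandwidth: float = DEFAULT_BANDWIDTH_NM,
    n_boot: int = 64,
) -> YieldPrediction:
    """Predict leg-placing yields on a (step size, fuel concentration) grid.

    The barrier difference at each step size is measured against the
    calibration reference step on the *flat* track (the reference stepping
    rate is an experimental, flat-origami quantity), converted to a stepping
    rate ``k_s(d) = k_s_ref * exp(-delta_dG(d))`` and pushed through the
    kinetic competition at each fuel concentration. Rows with zero contact
    probability get zero yield.
    """
    calibration = calibration or Calibration()
    if calibration.d_ref > max_reach(design):
        raise ValueError(
            f"reference step {calibration.d_ref} nm lies beyond the design reach "
            f"({max_reach(design):.1f} nm)"
        )
    kwargs = dict(n=n, grid_spacing=grid_spacing, bandwidth=bandwidth, n_boot=n_boot)
    seeds = np.random.SeedSequence(seed).spawn(2)

    def build(trk: TrackGeometry, sub_seed: np.random.SeedSequence):
        s = int(sub_seed.generate_state(1)[0] % 2**31)
        if hairpin is None:
            return ContactModel(design, trk, seed=s, **kwargs)
        return BlendedContactModel(apply_hairpin(design, hairpin), trk, seed=s, **kwargs)

    model = build(track, seeds[0])
    if track.kind == "flat":
        ref_model = model
    else:
        ref_model = build(TrackGeometry(kind="flat"), seeds[1])
    p_ref, se_ref = ref_model.probability(calibration.d_ref)
    if not p_ref > 0:
        raise SamplingFailureError("no contact at the reference step size; cannot calibrate")

    contact_rows = []
    curve_rows = []
    for d in d_grid:
        p, se = model.probability(d)
        dg = delta_barrier(p, p_ref)
        k_s = calibration.k_s_ref * (p / p_ref)
        if p > 0:
            se_dg = math.hypot(se / p, se_ref / p_ref)
        else:
            se_dg = math.inf
        contact_rows.append(
            dict(
                d_nm=d,
                p_contact=p,
                p_stderr=se,
                dG_rel_kBT=dg,
                k_s=k_s,
                n_samples=n,
                seed=seed,
            )
        )
        for f1 in F1_list:
            if p == 0.0:
                y, y_se = 0.0, 0.0
            else:
                y = yield_from_rates(KineticParams(k_s=k_s, k_FB=calibration.k_FB, F1=f1))
                y_se = y * (1.0 - y) * se_dg
            curve_rows.append(
                dict(
                    step_size_nm=d,
                    fuel_conc_M=f1,
                    **{"yield": y},
                    yield_se=y_se,
                    source="model",
                )
            )
    return YieldPrediction(
        curve=pd.DataFrame(curve_rows),
        contacts=pd.DataFrame(contact_rows),
        calibration=calibration,
        seed=seed,
        max_reach=max_reach(design, track),
    )
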