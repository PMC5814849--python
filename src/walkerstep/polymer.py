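"""Coarse polymer representation of the walker construct.

Each arm of the tethered system (the origami-bound walker body ending in the
free leg, and the foothold carrying the fuel strand) is an ordered chain of
segments. Duplex DNA segments are far below the ~50 nm double-strand
persistence length, so each is a single rigid rod of length
``n_bp * 0.34 nm``. Single-stranded segments are freely-jointed chains (FJC)
of Kuhn links (default Kuhn length 1.5 nm, contour 0.63 nm/nt); a partial
terminal link keeps its true, shorter length, and a segment shorter than one
Kuhn length is a single rigid link.

Conformations are sampled with uniformly random joint orientations and
rejected whenever any link penetrates the track surface (on the flat track
this reduces to the bead positions, since the allowed half-space is convex;
on the cylinder an exact rod-cylinder clearance test is used so links
cannot cut through the tube). The origami is a hard wall only: a flat
half-space or the outside of a cylinder (walker on the convex side).
Intra-chain excluded volume is ignored; the dominant geometric effect at
these densities is the wall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "SS_CONTOUR_NM_PER_NT",
    "SS_KUHN_NM",
    "DS_RISE_NM_PER_BP",
    "SegmentSpec",
    "ss_segment",
    "ds_segment",
    "arm_contour_length",
    "arm_link_lengths",
    "FlatSurface",
    "CylinderSurface",
    "BuriedAnchorError",
    "SamplingFailureError",
    "ChainSample",
    "sample_chain",
]

#: Contour length of single-stranded DNA per nucleotide (nm).
SS_CONTOUR_NM_PER_NT = 0.63
#: Kuhn length used for single-stranded DNA (nm).
SS_KUHN_NM = 1.5
#: Helical rise of duplex DNA per base pair (nm).
DS_RISE_NM_PER_BP = 0.34

#: Below this fraction of a Kuhn length a terminal remainder is folded into
#: the previous link rather than kept as a separate (numerically tiny) link.
_MIN_PARTIAL_FRACTION = 1e-9


class BuriedAnchorError(ValueError):
    """Raised when a chain anchor lies below the track surface."""


class SamplingFailureError(RuntimeError):
    """Raised when rejection sampling cannot produce any accepted conformation."""


@dataclass(frozen=True)
class SegmentSpec:
    """One ss or ds segment of an arm.

    ``n_units`` counts nucleotides for single-stranded segments and base
    pairs for duplexes. ``kuhn_length`` applies to single strands only.
    """

    kind: Literal["single_stranded", "duplex"]
    n_units: int
    contour_per_unit: float
    kuhn_length: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("single_stranded", "duplex"):
            raise ValueError(f"kind must be 'single_stranded' or 'duplex', got {self.kind!r}")
        if self.n_units < 1:
            raise ValueError(f"n_units must be >= 1, got {self.n_units!r}")
        if not self.contour_per_unit > 0:
            raise ValueError(f"contour_per_unit must be > 0, got {self.contour_per_unit!r}")
        if self.kind == "single_stranded":
            if self.kuhn_length is None or not self.kuhn_length > 0:
                raise ValueError("single_stranded segments need a positive kuhn_length")

    @property
    def contour(self) -> float:
        """Total contour length of the segment (nm)."""
        return self.n_units * self.contour_per_unit

    def link_lengths(self) -> np.ndarray:
        """Rigid-link decomposition of the segment (nm per link)."""
        if self.kind == "duplex":
            return np.array([self.contour])
        assert self.kuhn_length is not None
        n_full = int(math.floor(self.contour / self.kuhn_length))
        remainder = self.contour - n_full * self.kuhn_length
        if n_full == 0:
            # Shorter than one Kuhn length: a single rigid link.
            return np.array([self.contour])
        links = [self.kuhn_length] * n_full
        if remainder > _MIN_PARTIAL_FRACTION * self.kuhn_length:
            links.append(remainder)
        return np.array(links)


def ss_segment(
    n_nt: int,
    *,
    contour_per_nt: float = SS_CONTOUR_NM_PER_NT,
    kuhn_length: float = SS_KUHN_NM,
    name: str = "",
) -> SegmentSpec:
    """Single-stranded segment of ``n_nt`` nucleotides."""
    return SegmentSpec("single_stranded", n_nt, contour_per_nt, kuhn_length, name)


def ds_segment(n_bp: int, *, rise_per_bp: float = DS_RISE_NM_PER_BP, name: str = "") -> SegmentSpec:
    """Duplex segment of ``n_bp`` base pairs (one rigid rod)."""
    return SegmentSpec("duplex", n_bp, rise_per_bp, None, name)


def arm_contour_length(segments: Sequence[SegmentSpec]) -> float:
    """Total contour length of an arm (nm)."""
    return float(sum(seg.contour for seg in segments))


def arm_link_lengths(segments: Sequence[SegmentSpec]) -> np.ndarray:
    """Concatenated rigid-link lengths of an arm, anchor to reactive end."""
    if not segments:
        raise ValueError("an arm needs at least one segment")
    return np.concatenate([seg.link_lengths() for seg in segments])


@dataclass(frozen=True)
class FlatSurface:
    """Hard wall at z = 0; allowed half-space is z >= 0."""

    tol: float = 1e-9

    def allowed(self, points: np.ndarray) -> np.ndarray:
        return points[..., 2] >= -self.tol

    def segments_allowed(self, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        # The allowed half-space is convex: a segment clears the wall iff
        # both endpoints do.
        return self.allowed(starts) & self.allowed(ends)

    def anchor(self, arc_position: float = 0.0) -> np.ndarray:
        """Surface point at signed in-plane offset ``arc_position`` along x."""
        return np.array([arc_position, 0.0, 0.0])


@dataclass(frozen=True)
class CylinderSurface:
    """Hard cylindrical wall; the allowed region is outside the cylinder.

    The cylinder axis runs along y through (0, y, -radius), so the surface
    passes through the origin and is locally tangent to the z = 0 plane
    there; the walker sits on the convex side. Arc positions are measured
    around the circumference from the origin.
    """

    radius: float
    tol: float = 1e-9

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"radius must be > 0, got {self.radius!r}")

    def allowed(self, points: np.ndarray) -> np.ndarray:
        x = points[..., 0]
        z = points[..., 2] + self.radius
        return x * x + z * z >= (self.radius - self.tol) ** 2

    def segments_allowed(self, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Exact rod-cylinder clearance test.

        The region outside a cylinder is not convex, so a rigid link with
        both beads outside can still cut through the tube; the test uses the
        closest approach of the segment to the axis in the cross-sectional
        plane.
        """
        offset = np.array([0.0, 0.0, self.radius])
        a = (starts + offset)[..., [0, 2]]
        b = (ends + offset)[..., [0, 2]]
        d = b - a
        dd = np.einsum("...k,...k->...", d, d)
        ad = np.einsum("...k,...k->...", a, d)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(dd > 0, -ad / np.where(dd > 0, dd, 1.0), 0.0)
        np.clip(t, 0.0, 1.0, out=t)
        closest = a + t[..., None] * d
        dist2 = np.einsum("...k,...k->...", closest, closest)
        return dist2 >= (self.radius - self.tol) ** 2

    def anchor(self, arc_position: float = 0.0) -> np.ndarray:
        theta = arc_position / self.radius
        return np.array(
            [self.radius * math.sin(theta), 0.0, self.radius * math.cos(theta) - self.radius]
        )

    def rotate(self, points: np.ndarray, arc: float) -> np.ndarray:
        """Rotate points about the cylinder axis by an arc displacement."""
        theta = arc / self.radius
        c, s = math.cos(theta), math.sin(theta)
        x = points[..., 0]
        z = points[..., 2] + self.radius
        out = points.copy()
        out[..., 0] = c * x + s * z
        out[..., 2] = -s * x + c * z - self.radius
        return out


@dataclass
class ChainSample:
    """Accepted conformations of one arm.

    ``ends`` holds the reactive-end positions (n, 3); ``beads`` the full bead
    trajectories (n, n_links + 1, 3) when requested. ``acceptance_rate`` is
    the fraction of proposals whose beads all clear the surface.
    """

    ends: np.ndarray
    acceptance_rate: float
    anchor: np.ndarray
    link_lengths: np.ndarray
    seed: object
    beads: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.ends.shape[0]

    @property
    def contour_length(self) -> float:
        return float(self.link_lengths.sum())

    def radius_percentile(self, q: float = 95.0) -> float:
        """Percentile of the end distance from the anchor (nm)."""
        r = np.linalg.norm(self.ends - self.anchor, axis=1)
        return float(np.percentile(r, q))


def sample_chain(
    link_lengths: np.ndarray,
    n: int,
    rng: np.random.Generator,
    surface: FlatSurface | CylinderSurface | None = None,
    anchor: Sequence[float] = (0.0, 0.0, 0.0),
    keep_beads: bool = False,
    batch_size: int = 200_000,
    max_proposals: int = 500_000_000,
) -> ChainSample:
    """Rejection-sample chain conformations with a hard-wall surface.

    Joint orientations are independent and uniform on the sphere; a
    conformation is accepted only if every bead satisfies the surface
    constraint. Deterministic given the generator state.
    """
    lengths = np.asarray(link_lengths, dtype=float)
    if lengths.ndim != 1 or lengths.size == 0 or np.any(lengths <= 0):
        raise ValueError("link_lengths must be a non-empty 1-D array of positive lengths")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    anchor_arr = np.asarray(anchor, dtype=float)
    if surface is not None and not bool(np.all(surface.allowed(anchor_arr[None, :]))):
        raise BuriedAnchorError(f"anchor {anchor_arr.tolist()} lies below the track surface")

    n_links = lengths.size
    collected_ends: list[np.ndarray] = []
    collected_beads: list[np.ndarray] = []
    n_accepted = 0
    n_proposed = 0
    while n_accepted < n:
        if n_proposed >= max_proposals:
            raise SamplingFailureError(
                f"no usable conformations after {n_proposed} proposals "
                f"({n_accepted} accepted, {n} requested)"
            )
        m = min(batch_size, max_proposals - n_proposed)
        steps = rng.normal(size=(m, n_links, 3))
        norms = np.linalg.norm(steps, axis=2, keepdims=True)
        # A zero norm has probability 0; guard against it anyway.
        np.maximum(norms, 1e-300, out=norms)
        steps *= (lengths[None, :, None] / norms)
        beads = np.cumsum(steps, axis=1)
        beads += anchor_arr[None, None, :]
        if surface is None:
            ok = np.ones(m, dtype=bool)
        else:
            starts = np.concatenate(
                [np.broadcast_to(anchor_arr, (m, 1, 3)), beads[:, :-1, :]], axis=1
            )
            ok = surface.segments_allowed(starts, beads).all(axis=1)
        n_proposed += m
        if not ok.any():
            continue
        take = beads[ok]
        n_accepted += take.shape[0]
        collected_ends.append(take[:, -1, :].copy())
        if keep_beads:
            full = np.concatenate(
                [np.broadcast_to(anchor_arr, (take.shape[0], 1, 3)), take], axis=1
            )
            collected_beads.append(full)

    ends = np.concatenate(collected_ends)[:n]
    beads_out = np.concatenate(collected_beads)[:n] if keep_beads else None
    return ChainSample(
        ends=ends,
        acceptance_rate=n_accepted / n_proposed,
        anchor=anchor_arr,
        link_lengths=lengths,
        seed=None,
        beads=beads_out,
    )
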