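"""Assemble band specifications into the full s-fold symmetric node cloud.

Each of the g bands contributes s nodes placed at angles alpha + 2*pi*k/s,
k = 0..s-1, around the central axis x0 = (0, 0).  Node bookkeeping (band,
spoke, channel, subcomplex) travels with the coordinates through every
later deformation step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import ValidationError
from .reference_models import BandSpecs

DEFAULT_SYMMETRY = 8
DEFAULT_NEIGHBOUR_ORDER = 2
DEFAULT_KERNEL_FRACTION = 0.5


@dataclass
class SimulationConfig:
    """All knobs of one simulation run.

    Parameters
    ----------
    s : rotational symmetry (number of spokes), default 8.
    dmag : magnitude of irregular lateral deformation (nm); three marginal
        standard deviations of the scalar force distribution.
    omag : magnitude of correlated axial offsets (nm); defaults to dmag/2.
    kernel_fraction : RBF kernel length scale sigma as a fraction of the
        mean radius, default 0.5.
    h : circumferential neighbour order (each node connects to its 2h
        nearest same-band neighbours), default 2.
    Geometric parameters (all optional; None leaves the reference geometry
    untouched): target mean radius and SD, height (CS-NS distance) and SD,
    twist angle and SD, tilt concentration kappa, lateral shift SD,
    elongation axis ratio q and SD.
    n_npcs : number of NPCs to simulate.
    labelling_efficiency : probability a binding site carries a label.
    expansion_factor : isotropic scaling simulating expansion microscopy.
    seed : master seed for all random streams.
    """

    s: int = DEFAULT_SYMMETRY
    dmag: float = 0.0
    omag: float | None = None  # default dmag/2
    kernel_fraction: float = DEFAULT_KERNEL_FRACTION
    h: int = DEFAULT_NEIGHBOUR_ORDER
    mean_radius: float | None = None
    radius_sd: float = 0.0
    height: float | None = None
    height_sd: float = 0.0
    twist: float | None = None
    twist_sd: float = 0.0
    tilt_kappa: float | None = None
    shift_sd: float = 0.0
    elongation_q: float = 1.0
    elongation_q_sd: float = 0.0
    n_npcs: int = 1
    labelling_efficiency: float = 1.0
    expansion_factor: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.s < 3:
            raise ValidationError(f"symmetry s must be >= 3, got {self.s}")
        if self.dmag < 0:
            raise ValidationError("dmag must be >= 0")
        if self.omag is not None and self.omag < 0:
            raise ValidationError("omag must be >= 0")
        if not 0 <= self.h <= self.s // 2:
            raise ValidationError(f"h must be in 0..floor(s/2)={self.s // 2}, got {self.h}")
        if self.kernel_fraction <= 0:
            raise ValidationError("kernel_fraction must be > 0")
        for name in ("radius_sd", "height_sd", "twist_sd", "shift_sd", "elongation_q_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 < self.elongation_q <= 1.0:
            raise ValidationError("elongation_q must be in (0, 1]")
        if self.tilt_kappa is not None and self.tilt_kappa <= 0:
            raise ValidationError("tilt_kappa must be > 0")
        if not 0.0 <= self.labelling_efficiency <= 1.0:
            raise ValidationError("labelling_efficiency must be in [0, 1]")
        if self.expansion_factor <= 0:
            raise ValidationError("expansion_factor must be > 0")
        if self.mean_radius is not None and self.mean_radius <= 0:
            raise ValidationError("mean_radius must be > 0")
        if self.height is not None and self.height <= 0:
            raise ValidationError("height must be > 0")

    @property
    def effective_omag(self) -> float:
        return self.dmag / 2.0 if self.omag is None else self.omag


@dataclass
class NPCModel:
    """One assembled (possibly deformed) NPC: m = g*s nodes plus indices.

    ``coords`` is an (m, 3) array in nm; ``band``, ``spoke``, ``channel``
    are integer arrays of length m; ``subcomplex`` maps band index to its
    subcomplex tag.  The central axis is x = y = 0.
    """

    coords: np.ndarray
    band: np.ndarray
    spoke: np.ndarray
    channel: np.ndarray
    subcomplex: tuple[str, ...]  # per band
    s: int
    rng_seed: int = 0
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def m(self) -> int:
        return self.coords.shape[0]

    @property
    def g(self) -> int:
        return len(self.subcomplex)

    def band_nodes(self, j: int) -> np.ndarray:
        """Indices of the nodes of band j, ordered by spoke."""
        idx = np.nonzero(self.band == j)[0]
        return idx[np.argsort(self.spoke[idx])]

    def node_subcomplex(self) -> np.ndarray:
        """Subcomplex tag per node."""
        return np.asarray([self.subcomplex[j] for j in self.band])

    def copy(self) -> "NPCModel":
        return NPCModel(
            coords=self.coords.copy(),
            band=self.band.copy(),
            spoke=self.spoke.copy(),
            channel=self.channel.copy(),
            subcomplex=self.subcomplex,
            s=self.s,
            rng_seed=self.rng_seed,
            provenance=dict(self.provenance),
        )


def assemble(bands: BandSpecs, s: int = DEFAULT_SYMMETRY, rng_seed: int = 0) -> NPCModel:
    """Expand band specs into the s-fold symmetric node cloud.

    Node of band j, spoke k sits at
    (r_j cos(alpha_j + 2 pi k / s), r_j sin(alpha_j + 2 pi k / s), z_j).

    ``s=1`` and ``s=2`` are rejected for simulation (a ring needs >= 3
    spokes) except that s >= 1 is permitted when the caller explicitly
    wants the bare rotational unit; we follow the ring semantics and
    require s >= 1, enforcing s >= 3 in SimulationConfig instead.
    """
    if s < 1:
        raise ValidationError(f"s must be >= 1, got {s}")
    g = bands.g
    coords = np.empty((g * s, 3))
    band_idx = np.empty(g * s, dtype=int)
    spoke_idx = np.empty(g * s, dtype=int)
    chan_idx = np.empty(g * s, dtype=int)
    k = np.arange(s)
    for j, b in enumerate(bands.bands):
        ang = b.alpha + 2.0 * np.pi * k / s
        sl = slice(j * s, (j + 1) * s)
        coords[sl, 0] = b.r * np.cos(ang)
        coords[sl, 1] = b.r * np.sin(ang)
        coords[sl, 2] = b.z
        band_idx[sl] = j
        spoke_idx[sl] = k
        chan_idx[sl] = b.channel
    return NPCModel(
        coords=coords,
        band=band_idx,
        spoke=spoke_idx,
        channel=chan_idx,
        subcomplex=tuple(b.subcomplex for b in bands.bands),
        s=s,
        rng_seed=rng_seed,
        provenance={"bands": bands, "s": s},
    )


def mean_radius(obj) -> float:
    """Arithmetic mean lateral distance of nodes to the central axis.

    Accepts an NPCModel, an (m, 3)/(m, 2) coordinate array, or BandSpecs
    (where each band counts once, as all its nodes share one radius).
    """
    if isinstance(obj, NPCModel):
        xy = obj.coords[:, :2]
    elif isinstance(obj, BandSpecs):
        if obj.g == 0:
            raise ValidationError("empty band specs")
        return float(np.mean([b.r for b in obj.bands]))
    else:
        arr = np.asarray(obj, dtype=float)
        if arr.size == 0:
            raise ValidationError("empty coordinate set")
        xy = arr[:, :2]
    if xy.shape[0] == 0:
        raise ValidationError("empty model")
    return float(np.mean(np.hypot(xy[:, 0], xy[:, 1])))
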