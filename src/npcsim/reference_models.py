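"""Reference units: per-spoke label-site tables that seed every simulation.

A *rotational unit* (RU) holds the fluorophore attachment sites of one of
the ``s`` rotationally symmetric spokes of the NPC.  Each site is encoded
by an axial position ``z`` (nm), a radius ``r`` (nm) from the central axis,
an angle ``alpha`` (rad, relative to the other sites of the unit), and the
subcomplex it belongs to (cytoplasmic ring CR, inner ring IR, nucleoplasmic
ring NR, or the bridges BRCR/BRNR between them).

Tables derived from pseudoatomic PDB models are loaded from a small CSV
schema (see :func:`load_model_table`).  For self-contained tests and
examples, :func:`make_synthetic_ru` builds a unit from explicit lists and
:func:`default_two_ring_ru` provides a two-ring geometry emulating a
C-terminally tagged Nup96 label set.

Angle convention: ``alpha`` is measured counter-clockwise in the x-y plane
viewed from the cytoplasmic side; the cytoplasmic side is +z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, LookupError_, ValidationError

SUBCOMPLEXES = ("CR", "BRCR", "IR", "BRNR", "NR")
TERMINI = ("N", "C")

TABLE_COLUMNS = [
    "model_id",
    "nup_name",
    "terminus",
    "copy",
    "z",
    "r",
    "alpha",
    "subcomplex",
    "unit",
]

MAX_CHANNELS = 6


def _wrap_angle(a):
    """Wrap angle(s) to [-pi, pi)."""
    return np.mod(np.asarray(a, dtype=float) + np.pi, 2.0 * np.pi) - np.pi


@dataclass(frozen=True)
class LabelSite:
    """One fluorophore attachment site within a rotational unit."""

    nup_name: str
    terminus: str
    z: float  # nm
    r: float  # nm
    alpha: float  # rad, in [-pi, pi)
    subcomplex: str

    def __post_init__(self):
        if self.terminus not in TERMINI:
            raise ValidationError(f"terminus must be one of {TERMINI}, got {self.terminus!r}")
        if self.subcomplex not in SUBCOMPLEXES:
            raise ValidationError(
                f"subcomplex must be one of {SUBCOMPLEXES}, got {self.subcomplex!r}"
            )
        if not self.r > 0:
            raise ValidationError(f"radius must be positive, got {self.r}")
        if not (-np.pi <= self.alpha < np.pi):
            raise ValidationError(f"alpha must lie in [-pi, pi), got {self.alpha}")


@dataclass(frozen=True)
class ReferenceUnit:
    """Ordered label sites of one rotational unit, lengths in nm."""

    model_id: str
    sites: tuple[LabelSite, ...]
    length_unit_of_source: str = "nm"

    def __post_init__(self):
        if len(self.sites) == 0:
            raise ValidationError("a reference unit needs at least one site")
        seen = set()
        for s in self.sites:
            key = (s.nup_name, s.terminus, round(s.z, 9), round(s.alpha, 9))
            if key in seen:
                raise ValidationError(f"duplicate site {key}")
            seen.add(key)

    @property
    def g(self) -> int:
        return len(self.sites)

    def labels(self) -> list[tuple[str, str]]:
        """Distinct (nup_name, terminus) pairs in file order."""
        out = []
        for s in self.sites:
            if (s.nup_name, s.terminus) not in out:
                out.append((s.nup_name, s.terminus))
        return out


@dataclass(frozen=True)
class LabelSelection:
    """Up to six (nup_name, terminus) channels; the first may act as reference."""

    channels: tuple[tuple[str, str], ...]
    reference_is_first: bool = False

    def __post_init__(self):
        if not 1 <= len(self.channels) <= MAX_CHANNELS:
            raise ValidationError(
                f"number of channels must be in 1..{MAX_CHANNELS}, got {len(self.channels)}"
            )


@dataclass(frozen=True)
class Band:
    """One ring of ``s`` identical label sites: its geometry and bookkeeping."""

    z: float
    r: float
    alpha: float
    channel: int
    subcomplex: str


@dataclass(frozen=True)
class BandSpecs:
    """The g stacked bands produced by resolving a label selection."""

    bands: tuple[Band, ...]

    @property
    def g(self) -> int:
        return len(self.bands)

    def copy_number(self, s: int) -> int:
        """Whole-NPC copy number m = g*s."""
        return self.g * s


def load_model_table(path: str | Path, model_id: str | None = None) -> ReferenceUnit:
    """Load a reference unit from a delimiter-separated label-site table.

    The table must carry a header row with columns ``model_id, nup_name,
    terminus, copy, z, r, alpha, subcomplex, unit``.  Lengths are declared
    per-row by ``unit`` ("nm" or "angstrom"); angstrom values are divided
    by 10 on load so the returned unit is in nm.  Row order is preserved
    as band order.

    Parameters
    ----------
    path : path to the CSV file.
    model_id : optionally restrict to the rows of one model in a multi-model
        table; by default the file must contain a single model.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"model table not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"model table {path} is missing columns: {missing}")
    if model_id is not None:
        df = df[df["model_id"] == model_id]
        if df.empty:
            raise FormatError(f"model {model_id!r} not present in {path}")
    else:
        ids = df["model_id"].unique()
        if len(ids) != 1:
            raise FormatError(
                f"table holds models {list(ids)}; pass model_id= to pick one"
            )
        model_id = str(ids[0])

    dup = df.duplicated(subset=["nup_name", "terminus", "copy"])
    if dup.any():
        raise ValidationError(
            f"duplicate (nup_name, terminus, copy) rows in {path}: "
            f"{df.loc[dup, ['nup_name', 'terminus', 'copy']].to_dict('records')}"
        )

    units = set(df["unit"].astype(str))
    bad_units = units - {"nm", "angstrom"}
    if bad_units:
        raise FormatError(f"unknown length unit(s) {bad_units}; expected nm or angstrom")

    sites = []
    for row in df.itertuples(index=False):
        scale = 0.1 if row.unit == "angstrom" else 1.0
        r = float(row.r) * scale
        if r <= 0:
            raise ValidationError(f"non-positive radius {row.r} for {row.nup_name}")
        sites.append(
            LabelSite(
                nup_name=str(row.nup_name),
                terminus=str(row.terminus),
                z=float(row.z) * scale,
                r=r,
                alpha=float(_wrap_angle(row.alpha)),
                subcomplex=str(row.subcomplex),
            )
        )
    source_unit = "angstrom" if "angstrom" in units else "nm"
    return ReferenceUnit(model_id=model_id, sites=tuple(sites), length_unit_of_source=source_unit)


def write_model_table(ru: ReferenceUnit, path: str | Path) -> None:
    """Write a reference unit back to the table schema (always in nm).

    Round-trip contract: ``load_model_table(write_model_table(ru))``
    reproduces the unit exactly (values, order, tags).
    """
    rows = []
    copy_counter: dict[tuple[str, str], int] = {}
    for s in ru.sites:
        key = (s.nup_name, s.terminus)
        copy_counter[key] = copy_counter.get(key, 0) + 1
        rows.append(
            {
                "model_id": ru.model_id,
                "nup_name": s.nup_name,
                "terminus": s.terminus,
                "copy": copy_counter[key],
                "z": s.z,
                "r": s.r,
                "alpha": s.alpha,
                "subcomplex": s.subcomplex,
                "unit": "nm",
            }
        )
    pd.DataFrame(rows, columns=TABLE_COLUMNS).to_csv(path, index=False)


def make_synthetic_ru(
    g: int,
    z_list: Sequence[float],
    r_list: Sequence[float],
    alpha_list: Sequence[float],
    subcomplex_list: Sequence[str],
    nup_name: str = "SynNup",
    terminus: str = "N",
) -> ReferenceUnit:
    """Build a synthetic reference unit from explicit per-band values.

    All lists must have length ``g``; radii must be positive.  The result
    has ``model_id='synthetic'`` and passes every ReferenceUnit invariant,
    making it a drop-in stand-in for a PDB-derived table.
    """
    for name, lst in (
        ("z_list", z_list),
        ("r_list", r_list),
        ("alpha_list", alpha_list),
        ("subcomplex_list", subcomplex_list),
    ):
        if len(lst) != g:
            raise ValidationError(f"{name} has length {len(lst)}, expected g={g}")
    sites = tuple(
        LabelSite(
            nup_name=nup_name,
            terminus=terminus,
            z=float(z),
            r=float(r),
            alpha=float(_wrap_angle(a)),
            subcomplex=sc,
        )
        for z, r, a, sc in zip(z_list, r_list, alpha_list, subcomplex_list)
    )
    return ReferenceUnit(model_id="synthetic", sites=sites)


#: Default two-ring geometry: radius and inter-ring distance chosen to
#: emulate a C-terminally tagged Nup96 label set (one band in the CR, one
#: in the NR, 50 nm apart, lateral radius 53.7 nm).
DEFAULT_RING_RADIUS_NM = 53.7
DEFAULT_RING_SEPARATION_NM = 50.0


def default_two_ring_ru(
    radius: float = DEFAULT_RING_RADIUS_NM,
    separation: float = DEFAULT_RING_SEPARATION_NM,
    twist: float = 0.0,
) -> ReferenceUnit:
    """Synthetic two-ring reference unit (one CR band, one NR band).

    ``twist`` offsets the CR band angle relative to the NR band (rad).
    """
    return make_synthetic_ru(
        g=2,
        z_list=[separation / 2.0, -separation / 2.0],
        r_list=[radius, radius],
        alpha_list=[twist / 2.0, -twist / 2.0],
        subcomplex_list=["CR", "NR"],
        nup_name="SynNup96",
        terminus="C",
    )


def select_labels(ru: ReferenceUnit, sel: LabelSelection) -> BandSpecs:
    """Resolve a multi-channel label selection into band specifications.

    Every selected (nup, terminus) pair contributes all its copies in the
    unit as bands, tagged with the channel index.  Angles are then globally
    offset: for a single channel the mean alpha becomes 0; with a reference
    channel (the first listed), the reference channel's mean alpha becomes 0
    and all other channels shift by the same amount; without a reference,
    the pooled mean over all channels becomes 0.  Pairwise alpha differences
    within a channel are never changed.
    """
    bands: list[Band] = []
    for ch, (nup, term) in enumerate(sel.channels):
        matched = [s for s in ru.sites if s.nup_name == nup and s.terminus == term]
        if not matched:
            raise LookupError_(f"({nup}, {term}) not present in reference unit {ru.model_id}")
        for s in matched:
            bands.append(Band(z=s.z, r=s.r, alpha=s.alpha, channel=ch, subcomplex=s.subcomplex))

    alphas = np.array([b.alpha for b in bands])
    if len(sel.channels) == 1 or not sel.reference_is_first:
        shift = float(np.mean(alphas))
    else:
        ref_alphas = alphas[[i for i, b in enumerate(bands) if b.channel == 0]]
        shift = float(np.mean(ref_alphas))
    bands = [
        Band(
            z=b.z,
            r=b.r,
            alpha=float(_wrap_angle(b.alpha - shift)),
            channel=b.channel,
            subcomplex=b.subcomplex,
        )
        for b in bands
    ]
    return BandSpecs(bands=tuple(bands))


def bands_from_ru(ru: ReferenceUnit) -> BandSpecs:
    """Single-channel shortcut: select every site of the unit as one channel."""
    alphas = np.array([s.alpha for s in ru.sites])
    shift = float(np.mean(alphas))
    return BandSpecs(
        bands=tuple(
            Band(
                z=s.z,
                r=s.r,
                alpha=float(_wrap_angle(s.alpha - shift)),
                channel=0,
                subcomplex=s.subcomplex,
            )
            for s in ru.sites
        )
    )
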