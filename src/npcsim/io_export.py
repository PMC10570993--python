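"""Export: labelling efficiency, expansion factor, CSV and metadata files.

Coordinates are written in a CSV dialect chosen to map directly onto the
import tables of SMLM photophysics simulators: comma-separated, period
decimal, header row, lengths in nm, columns
``npc_id, channel, x_nm, y_nm, z_nm, band, spoke, node_id, kept``.
A "minimal" profile (x, y, z, channel) is available for consumers that
want nothing else.  Ground-truth features are computed before the
labelling-efficiency subsampling - they describe the structure, not the
label realization - and the exported `kept` rows let consumers recompute
label-limited features if they wish.
"""

from __future__ import annotations

import datetime
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from .feature_extraction import FeatureRecord
from .npc_assembly import NPCModel, SimulationConfig

COORD_COLUMNS = ["npc_id", "channel", "x_nm", "y_nm", "z_nm", "band", "spoke", "node_id", "kept"]
MINIMAL_COLUMNS = ["x_nm", "y_nm", "z_nm", "channel"]


def apply_labelling_efficiency(
    model: NPCModel, efficiency: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean keep-mask: each node labelled independently with p=efficiency.

    The kept count is Binomial(m, efficiency); efficiency 1 keeps all
    nodes and 0 none.
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValidationError(f"labelling efficiency must be in [0, 1], got {efficiency}")
    if efficiency == 1.0:
        return np.ones(model.m, dtype=bool)
    if efficiency == 0.0:
        return np.zeros(model.m, dtype=bool)
    return rng.uniform(size=model.m) < efficiency


def apply_expansion(coords: np.ndarray, factor: float) -> np.ndarray:
    """Isotropic scaling of coordinates, simulating expansion microscopy."""
    if factor <= 0:
        raise ValidationError(f"expansion factor must be > 0, got {factor}")
    return np.asarray(coords, dtype=float) * factor


def coordinates_frame(
    models: list[NPCModel],
    kept_masks: list[np.ndarray] | None = None,
    expansion_factor: float = 1.0,
    minimal: bool = False,
) -> pd.DataFrame:
    """One row per kept localization site across all NPCs."""
    rows = []
    for npc_id, model in enumerate(models):
        kept = np.ones(model.m, dtype=bool) if kept_masks is None else kept_masks[npc_id]
        coords = apply_expansion(model.coords, expansion_factor)
        for i in np.nonzero(kept)[0]:
            rows.append(
                {
                    "npc_id": npc_id,
                    "channel": int(model.channel[i]),
                    "x_nm": coords[i, 0],
                    "y_nm": coords[i, 1],
                    "z_nm": coords[i, 2],
                    "band": int(model.band[i]),
                    "spoke": int(model.spoke[i]),
                    "node_id": int(i),
                    "kept": True,
                }
            )
    df = pd.DataFrame(rows, columns=COORD_COLUMNS)
    return df[MINIMAL_COLUMNS] if minimal else df


def features_frames(
    features: list[list[FeatureRecord]],
) -> dict[str, pd.DataFrame]:
    """Split feature records into the three per-scope tables."""
    flat = [asdict(rec) for recs in features for rec in recs]
    df = pd.DataFrame(flat)
    return {
        "bands": df[df["scope"] == "band"].drop(columns=["scope"]).reset_index(drop=True),
        "subcomplexes": df[df["scope"] == "subcomplex"].drop(columns=["scope"]).reset_index(drop=True),
        "npcs": df[df["scope"] == "npc"].drop(columns=["scope"]).reset_index(drop=True),
    }


def write_run(
    outdir: str | Path,
    models: list[NPCModel],
    features: list[list[FeatureRecord]],
    config: SimulationConfig,
    kept_masks: list[np.ndarray] | None = None,
) -> dict[str, Path]:
    """Write a complete run: coordinates, metadata, three feature CSVs.

    Files (all re-loadable bit-exactly):
      coordinates.csv            one row per kept localization site
      metadata.yaml              config, master seed, version, per-NPC
                                 applied parameters, timestamp
      features_bands.csv         circle/ellipse features per band
      features_subcomplexes.csv  features per subcomplex (pooled bands)
      features_npcs.csv          per-NPC features (mean over bands) plus
                                 twist, height, and side tilts
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    coords = coordinates_frame(models, kept_masks, config.expansion_factor)
    paths["coordinates"] = outdir / "coordinates.csv"
    coords.to_csv(paths["coordinates"], index=False, float_format="%.9f")

    for name, frame in features_frames(features).items():
        p = outdir / f"features_{name}.csv"
        frame.to_csv(p, index=False, float_format="%.9f")
        paths[f"features_{name}"] = p

    meta = {
        "software": "npcsim",
        "version": __version__,
        "timestamp": datetime.datetime.now().isoformat(),
        "units": "nm",
        "config": {k: (v if not isinstance(v, np.generic) else v.item()) for k, v in vars(config).items()},
        "n_npcs": len(models),
        "per_npc": [
            {k: _plain(v) for k, v in m.provenance.items() if k != "bands"} for m in models
        ],
    }
    paths["metadata"] = outdir / "metadata.yaml"
    with open(paths["metadata"], "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return paths


def _plain(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v


def load_coordinates(path: str | Path) -> pd.DataFrame:
    """Load a coordinates CSV written by :func:`write_run`."""
    df = pd.read_csv(path)
    missing = [c for c in MINIMAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"coordinates file {path} lacks columns {missing}")
    return df
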