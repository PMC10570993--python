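"""Experiment harness: class datasets and the radius-variability sweep.

Two canned experiment shapes ship with the package:

* *Class datasets*: eight named variability classes (unmodified reference,
  smaller radius, smaller CR-NR distance, elongated, 14 deg twist, 9-fold
  symmetry, shifted sides, independently tilted sides), each simulated
  across a list of deformation magnitudes Dmag.

* *Radius sweep*: a cartesian sweep of the model radius SD (r_sigma) and
  Dmag - the two parameters that feed the variability of fitted NPC radii.
  Per cell, per-NPC radii are fitted (3D circle per band, averaged over
  bands), and the dataset SD is compared against a user-supplied
  real-data SD via the ratio sd_sim/sd_real - 1 (negative: too little
  simulated variability; positive: too much).

Real-data radius SDs are always user inputs; the harness never derives
them from microscopy data.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .feature_extraction import fit_circle_3d, npc_features, radius_sd_ratio
from .io_export import apply_labelling_efficiency, write_run
from .npc_assembly import SimulationConfig
from .reference_models import BandSpecs, bands_from_ru, default_two_ring_ru
from . import rng as rngmod
from .simulate import simulate_dataset, simulate_npc

logger = logging.getLogger("npcsim")

#: Default r_sigma (nm) and Dmag (nm) axes of the radius sweep.
SWEEP_RADIUS_SD = (0.0, 1.0, 2.0)
SWEEP_DMAG = (1.0, 10.0, 20.0)


def config_from_dict(d: dict, base: SimulationConfig | None = None) -> SimulationConfig:
    """Build a SimulationConfig from a plain mapping (e.g. parsed YAML).

    Accepts every SimulationConfig field plus the convenience key
    ``twist_deg`` (converted to radians).
    """
    d = dict(d)
    if "twist_deg" in d:
        if "twist" in d:
            raise ValidationError("give either twist or twist_deg, not both")
        d["twist"] = float(np.radians(d.pop("twist_deg")))
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if base is not None:
        merged = dict(vars(base))
        merged.update(d)
        d = merged
    return SimulationConfig(**d)


def load_class_presets(path: str | Path | None = None) -> dict[str, dict]:
    """Load the named class presets (the shipped file by default)."""
    if path is None:
        ref = resources.files("npcsim").joinpath("data/class_presets.yaml")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    presets = yaml.safe_load(text)
    if not isinstance(presets, dict):
        raise ValidationError("class preset file must map class names to parameter blocks")
    return {name: (block or {}) for name, block in presets.items()}


@dataclass
class ExperimentPlan:
    """A set of named classes and/or sweep axes over a base configuration."""

    base: SimulationConfig = field(default_factory=SimulationConfig)
    classes: dict[str, dict] = field(default_factory=dict)
    sweep: dict[str, list] = field(default_factory=dict)
    n_per_cell: int = 100
    seed: int = 0
    output_root: Path | None = None

    def cells(self) -> list[dict]:
        """Enumerate the cartesian sweep cells as override dicts."""
        cells = [{}]
        for param, values in self.sweep.items():
            cells = [{**c, param: v} for c in cells for v in values]
        return cells


def _cell_seed(master_seed: int, cell_index: int) -> int:
    """Derived per-cell seed, kept below 2**31."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(999, int(cell_index)))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_class_dataset(
    plan: ExperimentPlan,
    bands: BandSpecs | None = None,
    dmag_values: tuple[float, ...] = (0.0, 1.0, 5.0, 10.0, 15.0),
    write: bool = True,
) -> pd.DataFrame:
    """Simulate every class at every Dmag; return (and optionally write) a manifest.

    Per cell: ``plan.n_per_cell`` NPCs are simulated, features extracted,
    and (if ``write``) a complete run directory written under
    ``plan.output_root/<class>/dmag_<value>``.
    """
    if bands is None:
        bands = bands_from_ru(default_two_ring_ru())
    rows = []
    cell_index = 0
    for cname, overrides in plan.classes.items():
        for dmag in dmag_values:
            seed = _cell_seed(plan.seed, cell_index)
            config = config_from_dict(
                {**overrides, "dmag": dmag, "n_npcs": plan.n_per_cell, "seed": seed},
                base=plan.base,
            )
            logger.info("class %s dmag=%g seed=%d n=%d", cname, dmag, seed, plan.n_per_cell)
            models = simulate_dataset(bands, config)
            feats = [npc_features(m, npc_id=i) for i, m in enumerate(models)]
            outdir = None
            if write:
                if plan.output_root is None:
                    raise ValidationError("plan.output_root required when write=True")
                outdir = Path(plan.output_root) / cname / f"dmag_{dmag:g}"
                kept = [
                    apply_labelling_efficiency(
                        m, config.labelling_efficiency, rngmod.stream(seed, "labelling", i)
                    )
                    for i, m in enumerate(models)
                ]
                write_run(outdir, models, feats, config, kept_masks=kept)
            radii = [f[-1].circle_radius for f in feats]
            rows.append(
                {
                    "class": cname,
                    "dmag": dmag,
                    "seed": seed,
                    "n": plan.n_per_cell,
                    "mean_radius": float(np.mean(radii)),
                    "sd_radius": float(np.std(radii, ddof=1)) if len(radii) > 1 else 0.0,
                    "outdir": str(outdir) if outdir else "",
                }
            )
            cell_index += 1
    manifest = pd.DataFrame(rows)
    if write and plan.output_root is not None:
        manifest.to_csv(Path(plan.output_root) / "manifest.csv", index=False)
    return manifest


def fitted_radii(models, with_mean_of_bands: bool = True) -> np.ndarray:
    """Per-NPC radius: 3D circle fit per band, averaged over bands."""
    out = np.empty(len(models))
    for i, m in enumerate(models):
        radii = [fit_circle_3d(m.coords[m.band_nodes(j)]).radius for j in range(m.g)]
        out[i] = float(np.mean(radii))
    return out


def run_radius_sweep(
    base: SimulationConfig | None = None,
    bands: BandSpecs | None = None,
    radius_sd_values: tuple[float, ...] = SWEEP_RADIUS_SD,
    dmag_values: tuple[float, ...] = SWEEP_DMAG,
    n_per_cell: int = 1000,
    sd_real: float = 2.1,
    seed: int = 0,
) -> pd.DataFrame:
    """The r_sigma x Dmag sweep with the radius-SD comparison ratio.

    Per cell: ``n_per_cell`` ground-truth NPCs, per-NPC fitted radii, the
    dataset mean and SD, and the ratio sd_sim/sd_real - 1 against the
    user-supplied real-data SD (default 2.1 nm, the documented example for
    good-quality imaging).
    """
    if sd_real <= 0:
        raise ValidationError(f"sd_real must be > 0, got {sd_real}")
    if base is None:
        base = SimulationConfig()
    if bands is None:
        bands = bands_from_ru(default_two_ring_ru())
    rows = []
    cell_index = 0
    for rsd in radius_sd_values:
        for dmag in dmag_values:
            seed_cell = _cell_seed(seed, cell_index)
            config = config_from_dict(
                {"radius_sd": rsd, "dmag": dmag, "n_npcs": n_per_cell, "seed": seed_cell},
                base=base,
            )
            logger.info("sweep rsd=%g dmag=%g seed=%d n=%d", rsd, dmag, seed_cell, n_per_cell)
            models = simulate_dataset(bands, config)
            radii = fitted_radii(models)
            sd_sim = float(np.std(radii, ddof=1))
            rows.append(
                {
                    "radius_sd_model": rsd,
                    "dmag": dmag,
                    "seed": seed_cell,
                    "n": n_per_cell,
                    "mean_radius": float(np.mean(radii)),
                    "sd_radius": sd_sim,
                    "sd_ratio": radius_sd_ratio(sd_sim, sd_real),
                }
            )
            cell_index += 1
    return pd.DataFrame(rows)
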