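"""End-to-end simulation of single NPCs and datasets.

Order of application per NPC: symmetry change (discrete) -> radius scaling
-> height -> twist -> tilt -> shift (rigid motions) -> force-based
deformation (stochastic + elongation forces through the springs) -> axial
offsets.  Discrete and scaling operations come first, rigid motions next,
force-based deformation last; the order matters and is fixed here.

Per-NPC parameter draws (X' ~ N(X, sd^2)) and every other random
ingredient use named, independent streams derived from the master seed
(see rng.py), so toggling one variability type never changes another's
draws and reruns are bit-identical.
"""

from __future__ import annotations

import numpy as np

from . import rng as rngmod
from .geometric_variability import (
    apply_shift,
    apply_tilt,
    change_symmetry,
    draw_parameter,
    set_height,
    set_mean_radius,
    set_twist,
)
from .npc_assembly import NPCModel, SimulationConfig, assemble, mean_radius
from .reference_models import BandSpecs
from .spring_deformation import deform_npc

#: Rotational symmetry of the pseudoatomic reference models the band
#: tables derive from.
REFERENCE_SYMMETRY = 8


def simulate_npc(bands: BandSpecs, config: SimulationConfig, index: int = 0) -> NPCModel:
    """Simulate one NPC (index ``index``) under ``config``.

    Returns the deformed model; ``model.provenance`` records every applied
    parameter value for the metadata file.
    """
    rng_params = rngmod.stream(config.seed, "params", index)

    if config.s != REFERENCE_SYMMETRY:
        bands = change_symmetry(bands, REFERENCE_SYMMETRY, config.s)
    model = assemble(bands, s=config.s, rng_seed=config.seed)
    model.provenance["npc_index"] = index
    model.provenance["s"] = config.s

    # --- per-NPC geometric parameter draws (order of draws is fixed) ---
    target_r = config.mean_radius if config.mean_radius is not None else mean_radius(model)
    target_r = draw_parameter(target_r, config.radius_sd, rng_params)
    target_h = None
    if config.height is not None or config.height_sd > 0:
        base_h = config.height
        if base_h is None:
            from .feature_extraction import measure_height

            base_h = measure_height(model)
        target_h = draw_parameter(base_h, config.height_sd, rng_params)
    target_t = None
    if config.twist is not None or config.twist_sd > 0:
        base_t = 0.0 if config.twist is None else config.twist
        target_t = draw_parameter(base_t, config.twist_sd, rng_params)
    q = draw_parameter(config.elongation_q, config.elongation_q_sd, rng_params)
    q = float(np.clip(q, 1e-3, 1.0))

    # --- geometry ---
    if not np.isclose(target_r, mean_radius(model)):
        model = set_mean_radius(model, target_r)
    if target_h is not None:
        model = set_height(model, target_h)
    if target_t is not None:
        model = set_twist(model, target_t)
    if config.tilt_kappa is not None:
        model = apply_tilt(model, config.tilt_kappa, rngmod.stream(config.seed, "tilt", index))
    if config.shift_sd > 0:
        model = apply_shift(model, config.shift_sd, rngmod.stream(config.seed, "shift", index))

    # --- irregular deformation ---
    model = deform_npc(
        model,
        config,
        rng_forces=rngmod.stream(config.seed, "forces", index),
        rng_axial=rngmod.stream(config.seed, "axial", index),
        rng_elongation=rngmod.stream(config.seed, "elongation", index),
        elongation_q=q,
    )
    model.provenance["drawn_mean_radius"] = target_r
    if target_h is not None:
        model.provenance["drawn_height"] = target_h
    if target_t is not None:
        model.provenance["drawn_twist"] = target_t
    return model


def simulate_dataset(bands: BandSpecs, config: SimulationConfig) -> list[NPCModel]:
    """Simulate ``config.n_npcs`` NPCs with per-NPC independent streams."""
    return [simulate_npc(bands, config, index=i) for i in range(config.n_npcs)]
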