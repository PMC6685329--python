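"""Bundled study presets: healthy left ventricle and infarct border.

The presets encode the published summary constants of the Confetti
lineage-tracing experiment (recombination efficiency, fluorophore bias,
founder density, clone-size moments, singleton and EdU fractions,
monoclonal-vessel fractions) as simulator parameters; every derived
calibration (founder division probability, clone-size law, mixed-founder
vessel seeding rate, background EdU rate) is computed analytically in
:mod:`cloneatlas.params`.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .counts import SimCountsParams, build_archetypes
from .params import DivisionLaw, SimTissueParams

TISSUE_PRESETS = ("healthy", "mi")
_ALIASES = {"healthy": "healthy", "mi": "mi", "mi-border": "mi", "border": "mi"}


def load_preset_dict(name: str) -> dict:
    key = _ALIASES.get(name.lower())
    if key is None:
        raise KeyError(f"unknown preset {name!r}; available: {TISSUE_PRESETS}")
    ref = resources.files("cloneatlas").joinpath(f"data/presets/{key}.yaml")
    return yaml.safe_load(ref.read_text())


def tissue_preset(name: str, seed: int | None = None, n_sections: int = 30, **overrides) -> SimTissueParams:
    """Build :class:`SimTissueParams` for a named preset (``healthy`` / ``mi``)."""
    raw = load_preset_dict(name)
    raw.pop("name", None)
    law = raw.pop("division_law")
    # Published fluorophore fractions are means over animals and do not sum
    # exactly to 1; renormalize to a probability vector.
    cp = [float(x) for x in raw.pop("colour_probs")]
    total = sum(cp)
    params = dict(
        division_law=DivisionLaw(**law),
        colour_probs=tuple(x / total for x in cp),
        n_sections=n_sections,
        seed=seed,
        **raw,
    )
    params.update(overrides)
    return SimTissueParams(**params)


def counts_preset(seed: int | None = None, **overrides) -> SimCountsParams:
    """Default ten-archetype count-simulator parameters."""
    params = dict(archetypes=build_archetypes(), seed=seed)
    params.update(overrides)
    return SimCountsParams(**params)
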