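"""The three demographic model topologies for the European scallop system.

All models share three sampled demes — the Atlantic (ATL) and Norwegian
(NOR) groups of *Pecten maximus* and the Mediterranean *P. jacobeus* (JAC)
— and differ in how the two *P. maximus* groups originated:

``M1_two_refugia``
    ATL and NOR split from the ancestral *P. maximus* lineage ``t_div``
    generations ago and each expanded from its own (refugial) historical
    size.  *P. jacobeus* split off ``t_dmj`` generations ago.  9 free
    parameters (no ``t_exp``).

``M2_single_refugium``
    The *P. maximus* lineage began expanding from a single refugium
    ``t_exp`` generations ago; the Norwegian group was founded ``t_div``
    generations ago by a founder event out of the expanding lineage.
    10 free parameters.

``M3_single_refugium_no_growth``
    As M2, but the lineage size is held constant between ``t_exp`` and
    ``t_div`` (a geographic expansion leaving a bottleneck-like plateau);
    growth of the two groups happens only after ``t_div``, which is
    expected to be more recent.  10 free parameters.

Sizes are diploid effective sizes; times are generations before present.
Growth between historical and contemporary sizes is exponential.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .coalescent import DemeConfig, DemographyEvent

__all__ = [
    "ModelSpec", "model_spec", "MODEL_IDS",
    "DEFAULT_M1_PARAMS", "DEFAULT_M2_PARAMS", "DEFAULT_M3_PARAMS",
    "DEFAULT_SAMPLES", "DEFAULT_BOUNDS",
]

MODEL_IDS = ("M1_two_refugia", "M2_single_refugium", "M3_single_refugium_no_growth")

_SIZE_NAMES = ("Ne_hist_JAC", "Ne_cur_JAC", "Ne_hist_MAX",
               "Ne_hist_ATL", "Ne_cur_ATL", "Ne_hist_NOR", "Ne_cur_NOR")

#: log-uniform prior bounds; times span 1e2-5e5 generations, sizes 1e2-1e6
#: diploids, wide enough to cover every default point value below.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "t_dmj": (100.0, 5e5),
    "t_div": (100.0, 5e5),
    "t_exp": (100.0, 5e5),
    **{n: (100.0, 1e6) for n in _SIZE_NAMES},
}

#: default haploid sample sizes per deme used for SFS-based inference
DEFAULT_SAMPLES: dict[str, int] = {"ATL": 20, "NOR": 20, "JAC": 20}

#: canonical parameter point for the two-refugia model; divergence times are
#: the study system's point estimates (~3,700 and ~95,000 generations) and
#: sizes were calibrated once against the simulator so that between-lineage
#: Weir-Cockerham FST falls in the observed ranges (0.02-0.05 within
#: P. maximus, 0.03-0.09 between species).
DEFAULT_M1_PARAMS: dict[str, float] = {
    "t_dmj": 95_000.0,
    "t_div": 3_700.0,
    "Ne_hist_JAC": 800_000.0,
    "Ne_cur_JAC": 900_000.0,
    "Ne_hist_MAX": 750_000.0,
    "Ne_hist_ATL": 20_000.0,
    "Ne_cur_ATL": 200_000.0,
    "Ne_hist_NOR": 60_000.0,
    "Ne_cur_NOR": 120_000.0,
}

DEFAULT_M2_PARAMS: dict[str, float] = {
    **DEFAULT_M1_PARAMS,
    "t_exp": 12_000.0,
    "Ne_hist_ATL": 8_000.0,
    "Ne_hist_NOR": 2_000.0,  # founder size of the Norwegian group
}

DEFAULT_M3_PARAMS: dict[str, float] = {
    **DEFAULT_M1_PARAMS,
    "t_exp": 12_000.0,
    "t_div": 1_500.0,
    "Ne_hist_ATL": 8_000.0,
    "Ne_hist_NOR": 2_000.0,
}


@dataclass
class ModelSpec:
    """A demographic model topology plus priors and fixed parameters."""

    model_id: str
    param_names: tuple[str, ...]
    builder: Callable[[dict[str, float], dict[str, int]], tuple[list, list]]
    bounds: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    fixed: dict[str, float] = field(default_factory=dict)
    sample_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SAMPLES))

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.param_names if n not in self.fixed)

    @property
    def k(self) -> int:
        """Number of free parameters entering the AIC penalty."""
        return len(self.free_names)

    def full_params(self, free_values: dict[str, float]) -> dict[str, float]:
        params = dict(self.fixed)
        params.update(free_values)
        missing = set(self.param_names) - set(params)
        if missing:
            raise ValueError(f"missing parameters: {sorted(missing)}")
        return params

    def valid(self, params: dict[str, float]) -> bool:
        """Time-ordering and expansion constraints of the topology.

        All three models assume post-glacial population expansion, so each
        deme's contemporary size must exceed its historical (refugial or
        founder) size.
        """
        if params["t_dmj"] <= params["t_div"]:
            return False
        if "t_exp" in self.param_names:
            if not params["t_div"] < params["t_exp"] < params["t_dmj"]:
                return False
        for deme in ("ATL", "NOR", "JAC"):
            if params[f"Ne_cur_{deme}"] <= params[f"Ne_hist_{deme}"]:
                return False
        return all(v > 0 for v in params.values())

    def demography(self, params: dict[str, float]):
        if not self.valid(params):
            raise ValueError(f"invalid parameters for {self.model_id}: {params}")
        return self.builder(params, self.sample_sizes)


def _build_m1(p: dict[str, float], samples: dict[str, int]):
    demes = [
        DemeConfig("ATL", samples["ATL"], p["Ne_cur_ATL"], p["Ne_hist_ATL"], p["t_div"]),
        DemeConfig("NOR", samples["NOR"], p["Ne_cur_NOR"], p["Ne_hist_NOR"], p["t_div"]),
        DemeConfig("JAC", samples["JAC"], p["Ne_cur_JAC"], p["Ne_hist_JAC"], p["t_dmj"]),
    ]
    events = [
        DemographyEvent(p["t_div"], "merge_demes", source="NOR", dest="ATL"),
        DemographyEvent(p["t_div"], "set_size", dest="ATL", new_size=p["Ne_hist_MAX"]),
        DemographyEvent(p["t_dmj"], "merge_demes", source="ATL", dest="JAC"),
    ]
    return demes, events


def _build_m2(p: dict[str, float], samples: dict[str, int]):
    # ATL carries the single-refugium P. maximus lineage: expansion from the
    # refugial size Ne_hist_ATL begins t_exp ago; NOR is founded at t_div
    # with founder size Ne_hist_NOR.
    demes = [
        DemeConfig("ATL", samples["ATL"], p["Ne_cur_ATL"], p["Ne_hist_ATL"], p["t_exp"]),
        DemeConfig("NOR", samples["NOR"], p["Ne_cur_NOR"], p["Ne_hist_NOR"], p["t_div"]),
        DemeConfig("JAC", samples["JAC"], p["Ne_cur_JAC"], p["Ne_hist_JAC"], p["t_dmj"]),
    ]
    events = [
        DemographyEvent(p["t_div"], "merge_demes", source="NOR", dest="ATL"),
        DemographyEvent(p["t_exp"], "set_size", dest="ATL", new_size=p["Ne_hist_MAX"]),
        DemographyEvent(p["t_dmj"], "merge_demes", source="ATL", dest="JAC"),
    ]
    return demes, events


def _build_m3(p: dict[str, float], samples: dict[str, int]):
    # Single refugium, but no growth between t_exp and t_div: the lineage
    # plateaus at Ne_hist_ATL over (t_div, t_exp); ATL growth starts at t_div.
    demes = [
        DemeConfig("ATL", samples["ATL"], p["Ne_cur_ATL"], p["Ne_hist_ATL"], p["t_div"]),
        DemeConfig("NOR", samples["NOR"], p["Ne_cur_NOR"], p["Ne_hist_NOR"], p["t_div"]),
        DemeConfig("JAC", samples["JAC"], p["Ne_cur_JAC"], p["Ne_hist_JAC"], p["t_dmj"]),
    ]
    events = [
        DemographyEvent(p["t_div"], "merge_demes", source="NOR", dest="ATL"),
        DemographyEvent(p["t_exp"], "set_size", dest="ATL", new_size=p["Ne_hist_MAX"]),
        DemographyEvent(p["t_dmj"], "merge_demes", source="ATL", dest="JAC"),
    ]
    return demes, events


_BUILDERS = {
    "M1_two_refugia": (_build_m1, ("t_dmj", "t_div") + _SIZE_NAMES),
    "M2_single_refugium": (_build_m2, ("t_dmj", "t_div", "t_exp") + _SIZE_NAMES),
    "M3_single_refugium_no_growth": (_build_m3, ("t_dmj", "t_div", "t_exp") + _SIZE_NAMES),
}


def model_spec(model_id: str, fixed: dict[str, float] | None = None,
               sample_sizes: dict[str, int] | None = None,
               bounds: dict[str, tuple[float, float]] | None = None) -> ModelSpec:
    """Construct a :class:`ModelSpec` for one of the three model ids
    (``M1``/``M2``/``M3`` prefixes are accepted)."""
    matches = [m for m in MODEL_IDS if m == model_id or m.startswith(model_id)]
    if len(matches) != 1:
        raise ValueError(f"unknown model id {model_id!r}")
    builder, names = _BUILDERS[matches[0]]
    b = dict(DEFAULT_BOUNDS)
    if matches[0] == "M3_single_refugium_no_growth":
        # t_div is expected to be more recent under M3
        b["t_div"] = (b["t_div"][0], b["t_div"][1] / 2)
    if bounds:
        b.update(bounds)
    return ModelSpec(matches[0], names, builder, b,
                     dict(fixed or {}), dict(sample_sizes or DEFAULT_SAMPLES))
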