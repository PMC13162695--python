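"""Registry of the ten competing demographic scenarios.

Five models for the origin of the focal Tibetan group (TT):

* TT1 — TT splits from the northern wild boars (NAW) after the NAW/SAW
  divergence.
* TT2 — TT splits from the southern wild boars (SAW).
* TT3 — TT splits from NAW and later receives a gene-flow pulse from SAW.
* TT4 — TT splits from SAW and later receives a pulse from NAW.
* TT5 — TT is founded instantaneously by admixture between SAW and NAW;
  ``alpha`` is the SAW-derived ancestry fraction (alpha = 0 degenerates to a
  pure NAW origin, alpha = 1 to a pure SAW origin).

Five models for a derived Tibetan group X (GST / YNT / SCT stand-ins), all on
top of a fixed TT admixture founding:

* X1 — X splits from TT after TT's founding.
* X2 — X has its own admixed origin, older than TT's.
* X3 — X splits independently from NAW after TT's founding.
* X4 — X splits independently from SAW after TT's founding.
* X5 — X has its own admixed origin, younger than TT's.

All templates share a fixed deep scaffold (outgroup split, western Eurasian
split, NAW/SAW divergence) so composite likelihoods are comparable; only the
TT/X-relevant parameters are free.  Ne and times are searched on a log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from suspop.simgen import SCAFFOLD, DemographicModel, Event

MODEL_IDS = [f"TT{i}" for i in range(1, 6)] + [f"X{i}" for i in range(1, 6)]


@dataclass
class ModelTemplate:
    model_id: str
    param_names: list[str]
    lower: np.ndarray
    upper: np.ndarray
    log_scale: np.ndarray
    builder: Callable[[np.ndarray], DemographicModel]
    defaults: np.ndarray
    constraints: list[tuple[str, Callable[[np.ndarray], bool]]] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.param_names)

    def default_vector(self) -> np.ndarray:
        return self.defaults.copy()

    def build(self, vector) -> DemographicModel:
        vector = np.asarray(vector, dtype=float)
        report = validate_parameters(self, vector)
        if report:
            raise ValueError(f"{self.model_id}: " + "; ".join(report))
        return self.builder(vector)

    def random_vector(self, rng: np.random.Generator) -> np.ndarray:
        """Uniform draw within bounds, log-uniform on log-scale parameters."""
        with np.errstate(divide="ignore", invalid="ignore"):
            lo = np.where(self.log_scale, np.log10(self.lower), self.lower)
            hi = np.where(self.log_scale, np.log10(self.upper), self.upper)
        x = rng.uniform(lo, hi)
        return np.where(self.log_scale, 10.0**x, x)


def validate_parameters(template: ModelTemplate, vector) -> list[str]:
    """Bounds and ordering checks; empty list means ok."""
    vector = np.asarray(vector, dtype=float)
    report = []
    if vector.shape != (template.k,):
        return [f"length: expected {template.k} parameters, got {vector.shape}"]
    bad = (vector < template.lower) | (vector > template.upper)
    for name, flag in zip(template.param_names, bad):
        if flag:
            report.append(f"bounds: {name} outside "
                          f"[{template.lower[template.param_names.index(name)]}, "
                          f"{template.upper[template.param_names.index(name)]}]")
    for name, ok in template.constraints:
        if not ok(vector):
            report.append(f"ordering: {name}")
    return report


# ---------------------------------------------------------------------------
# scaffold
# ---------------------------------------------------------------------------

def _base_populations(with_x: bool, n_tt: float, n_x: float | None = None) -> dict:
    s = SCAFFOLD
    pops = {
        "CEB": s["N_CEB"],
        "WEW": s["N_WEW"],
        "NAW": s["N_NAW"],
        "SAW": s["N_SAW"],
        "TT": n_tt,
    }
    if with_x:
        pops["X"] = n_x if n_x is not None else s["N_X"]
    return pops


def _deep_events() -> list[Event]:
    """Fixed rootward structure: SAW joins NAW, then WEW, then the outgroup."""
    s = SCAFFOLD
    return [
        Event(time=s["T_NS"], kind="split", derived="SAW", ancestral="NAW"),
        Event(time=s["T_NS"], kind="size_change", population="NAW", size=s["N_ANC"]),
        Event(time=s["T_WEW"], kind="split", derived="WEW", ancestral="NAW"),
        Event(time=s["T_CEB"], kind="split", derived="CEB", ancestral="NAW"),
    ]


def _sorted_model(pops: dict, events: list[Event]) -> DemographicModel:
    events = sorted(events, key=lambda e: e.time)  # stable: same-time order kept
    m = DemographicModel(populations=pops, events=events)
    m.validate()
    return m


def _tt_founding_events(n_tt: float, t_tt: float, alpha: float) -> list[Event]:
    """TT founded at t_tt by admixture: fraction alpha from SAW, rest from NAW."""
    ev = []
    if alpha > 0:
        ev.append(Event(time=t_tt, kind="admixture_pulse",
                        recipient="TT", donor="SAW", alpha=alpha))
    ev.append(Event(time=t_tt, kind="split", derived="TT", ancestral="NAW"))
    return ev


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _build_tt_split(source: str):
    def build(v: np.ndarray) -> DemographicModel:
        n_tt, t_tt = v
        events = [Event(time=t_tt, kind="split", derived="TT", ancestral=source)]
        return _sorted_model(_base_populations(False, n_tt), events + _deep_events())
    return build


def _build_tt_pulse(split_source: str, pulse_donor: str):
    def build(v: np.ndarray) -> DemographicModel:
        n_tt, t_tt, r, alpha = v
        events = [
            Event(time=r * t_tt, kind="admixture_pulse",
                  recipient="TT", donor=pulse_donor, alpha=alpha),
            Event(time=t_tt, kind="split", derived="TT", ancestral=split_source),
        ]
        return _sorted_model(_base_populations(False, n_tt), events + _deep_events())
    return build


def _build_tt_admix(v: np.ndarray) -> DemographicModel:
    n_tt, t_tt, alpha = v
    return _sorted_model(
        _base_populations(False, n_tt),
        _tt_founding_events(n_tt, t_tt, alpha) + _deep_events(),
    )


def _fixed_tt_events() -> list[Event]:
    s = SCAFFOLD
    return _tt_founding_events(s["N_TT"], s["T_TT"], s["ALPHA_TT"])


def _build_x_split(source: str):
    def build(v: np.ndarray) -> DemographicModel:
        n_x, t_x = v
        events = [Event(time=t_x, kind="split", derived="X", ancestral=source)]
        return _sorted_model(
            _base_populations(True, SCAFFOLD["N_TT"], n_x),
            events + _fixed_tt_events() + _deep_events(),
        )
    return build


def _build_x_admix(v: np.ndarray) -> DemographicModel:
    n_x, t_x, alpha = v
    events = []
    if alpha > 0:
        events.append(Event(time=t_x, kind="admixture_pulse",
                            recipient="X", donor="SAW", alpha=alpha))
    events.append(Event(time=t_x, kind="split", derived="X", ancestral="NAW"))
    return _sorted_model(
        _base_populations(True, SCAFFOLD["N_TT"], n_x),
        events + _fixed_tt_events() + _deep_events(),
    )


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

_NE_LO, _NE_HI = 1e2, 1e6
_T_LO = 10.0


def _templates() -> dict[str, ModelTemplate]:
    s = SCAFFOLD
    t_ns, t_tt = s["T_NS"], s["T_TT"]
    reg: dict[str, ModelTemplate] = {}

    def add(model_id, names, lower, upper, log, builder, defaults, constraints=()):
        reg[model_id] = ModelTemplate(
            model_id=model_id,
            param_names=list(names),
            lower=np.asarray(lower, float),
            upper=np.asarray(upper, float),
            log_scale=np.asarray(log, bool),
            builder=builder,
            defaults=np.asarray(defaults, float),
            constraints=list(constraints),
        )

    tt_time_hi = 0.95 * t_ns
    order_tt = [("T_TT < T_NAW_SAW_divergence", lambda v: v[1] < t_ns)]
    add("TT1", ["N_TT", "T_TT"], [_NE_LO, _T_LO], [_NE_HI, tt_time_hi],
        [True, True], _build_tt_split("NAW"), [s["N_TT"], t_tt], order_tt)
    add("TT2", ["N_TT", "T_TT"], [_NE_LO, _T_LO], [_NE_HI, tt_time_hi],
        [True, True], _build_tt_split("SAW"), [s["N_TT"], t_tt], order_tt)
    # pulse strictly after the founding split: time ratio r capped at 0.9
    add("TT3", ["N_TT", "T_TT", "r_pulse", "alpha"],
        [_NE_LO, _T_LO, 0.05, 0.0], [_NE_HI, tt_time_hi, 0.9, 1.0],
        [True, True, False, False], _build_tt_pulse("NAW", "SAW"),
        [s["N_TT"], t_tt, 0.5, 0.3], order_tt)
    add("TT4", ["N_TT", "T_TT", "r_pulse", "alpha"],
        [_NE_LO, _T_LO, 0.05, 0.0], [_NE_HI, tt_time_hi, 0.9, 1.0],
        [True, True, False, False], _build_tt_pulse("SAW", "NAW"),
        [s["N_TT"], t_tt, 0.5, 0.3], order_tt)
    add("TT5", ["N_TT", "T_TT", "alpha"],
        [_NE_LO, _T_LO, 0.0], [_NE_HI, tt_time_hi, 1.0],
        [True, True, False], _build_tt_admix,
        [s["N_TT"], t_tt, s["ALPHA_TT"]], order_tt)

    x_recent_hi = 0.95 * t_tt
    order_recent = [("T_X < T_TT_founding", lambda v: v[1] < t_tt)]
    order_older = [("T_TT_founding < T_X < T_NAW_SAW_divergence",
                    lambda v: t_tt < v[1] < t_ns)]
    add("X1", ["N_X", "T_X"], [_NE_LO, _T_LO], [_NE_HI, x_recent_hi],
        [True, True], _build_x_split("TT"), [s["N_X"], s["T_X"]], order_recent)
    add("X2", ["N_X", "T_X", "alpha_X"],
        [_NE_LO, 1.05 * t_tt, 0.0], [_NE_HI, 0.95 * t_ns, 1.0],
        [True, True, False], _build_x_admix,
        [s["N_X"], 2.0 * t_tt, 0.5], order_older)
    add("X3", ["N_X", "T_X"], [_NE_LO, _T_LO], [_NE_HI, x_recent_hi],
        [True, True], _build_x_split("NAW"), [s["N_X"], s["T_X"]], order_recent)
    add("X4", ["N_X", "T_X"], [_NE_LO, _T_LO], [_NE_HI, x_recent_hi],
        [True, True], _build_x_split("SAW"), [s["N_X"], s["T_X"]], order_recent)
    add("X5", ["N_X", "T_X", "alpha_X"],
        [_NE_LO, _T_LO, 0.0], [_NE_HI, x_recent_hi, 1.0],
        [True, True, False], _build_x_admix,
        [s["N_X"], s["T_X"], 0.5], order_recent)
    return reg


_REGISTRY = _templates()


def get_template(model_id: str) -> ModelTemplate:
    try:
        return _REGISTRY[model_id]
    except KeyError:
        raise ValueError(f"unknown model id {model_id!r}; known: {MODEL_IDS}") from None
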