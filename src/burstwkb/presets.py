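"""Bundled parameter presets for the four worked example regimes.

All presets share s_max = 20 (twice the maximal mean production rate) and the
feedback threshold s_thresh = 6:

* ``neg_fb_fig1`` -- negative feedback, fixed burst size 1, a0 = 10, a1 = 2
* ``pos_fb_fig1`` -- positive feedback, fixed burst size 1, a0 = 2, a1 = 10
* ``neg_fb_fig3`` -- negative feedback, fixed burst size 4, a0 = 2.5, a1 = 0.5
  (monostable)
* ``pos_fb_fig4`` -- positive feedback, fixed burst size 4, a0 = 0.5, a1 = 2.5
  (bistable)
* ``fano_sweep_fig2`` -- positive feedback with mean burst size 1 and a sweep
  of the burst Fano factor (potential-level analysis; non-integer binomial
  trial counts are handled at the MGF level)
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import ModelSpec, make_burst_distribution, make_step_response

__all__ = ["Preset", "load_preset", "PRESET_NAMES"]

DEFAULT_EPSILONS = (0.1, 0.05, 0.02)


@dataclass(frozen=True)
class Preset:
    name: str
    burst_mean: float
    burst_fano: float
    s_thresh: int
    a0: float
    a1: float
    s_max: int = 20
    epsilon_list: tuple[float, ...] = DEFAULT_EPSILONS
    fano_list: tuple[float, ...] | None = None

    def model(self, epsilon: float, fano: float | None = None) -> ModelSpec:
        fano = self.burst_fano if fano is None else fano
        needs_mgf_only = 0.0 < fano < 1.0 and (
            abs(self.burst_mean / (1.0 - fano) - round(self.burst_mean / (1.0 - fano)))
            > 1e-9
        )
        burst = make_burst_distribution(self.burst_mean, fano, mgf_only=needs_mgf_only)
        feedback = make_step_response(self.s_max, self.s_thresh, self.a0, self.a1)
        return ModelSpec(burst=burst, feedback=feedback, s_max=self.s_max, epsilon=epsilon)


_PRESETS = {
    "neg_fb_fig1": Preset("neg_fb_fig1", 1.0, 0.0, 6, 10.0, 2.0),
    "pos_fb_fig1": Preset("pos_fb_fig1", 1.0, 0.0, 6, 2.0, 10.0),
    "neg_fb_fig3": Preset("neg_fb_fig3", 4.0, 0.0, 6, 2.5, 0.5),
    "pos_fb_fig4": Preset("pos_fb_fig4", 4.0, 0.0, 6, 0.5, 2.5),
    "fano_sweep_fig2": Preset(
        "fano_sweep_fig2", 1.0, 0.0, 6, 2.0, 10.0, fano_list=(0.0, 0.25, 0.5, 0.75)
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def load_preset(name: str) -> Preset:
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None
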