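"""YAML model configuration.

Layout::

    burst:
      mean: 4        # with fano -- the mean/Fano MGF family
      fano: 0
      # pmf: [0.0, 0.5, 0.5]   # alternatively, an explicit pmf
    feedback:
      s_thresh: 6    # step response, or
      a0: 0.5
      a1: 2.5
      # rates: [..]  # an explicit table of length s_max + 1
    model:
      s_max: auto    # integer, or "auto" for the two-times-max-rate rule
      epsilon: 0.05
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .model import (
    ModelSpec,
    choose_smax,
    explicit_burst_distribution,
    explicit_response,
    make_burst_distribution,
    make_step_response,
)

__all__ = ["model_from_dict", "load_config", "model_to_dict", "dump_config"]


class ConfigError(ValueError):
    pass


def _section(cfg: dict, name: str) -> dict:
    try:
        sec = cfg[name]
    except (KeyError, TypeError):
        raise ConfigError(f"missing config section [{name}]") from None
    if not isinstance(sec, dict):
        raise ConfigError(f"config section [{name}] must be a mapping")
    return sec


def model_from_dict(cfg: dict) -> ModelSpec:
    burst_cfg = _section(cfg, "burst")
    fb_cfg = _section(cfg, "feedback")
    model_cfg = _section(cfg, "model")

    if "pmf" in burst_cfg:
        burst = explicit_burst_distribution(burst_cfg["pmf"])
    elif "mean" in burst_cfg and "fano" in burst_cfg:
        burst = make_burst_distribution(
            float(burst_cfg["mean"]), float(burst_cfg["fano"])
        )
    else:
        raise ConfigError("burst section needs either 'pmf' or 'mean' and 'fano'")

    if "epsilon" not in model_cfg:
        raise ConfigError("model section needs 'epsilon'")
    epsilon = float(model_cfg["epsilon"])

    s_max_cfg = model_cfg.get("s_max", "auto")
    if "rates" in fb_cfg:
        feedback = explicit_response(fb_cfg["rates"])
        s_max = feedback.s_max
        if s_max_cfg != "auto" and int(s_max_cfg) != s_max:
            raise ConfigError(
                "model.s_max conflicts with the length of feedback.rates"
            )
    else:
        for key in ("s_thresh", "a0", "a1"):
            if key not in fb_cfg:
                raise ConfigError(f"feedback section needs '{key}' (or 'rates')")
        if s_max_cfg == "auto":
            s_max = choose_smax(burst, max(float(fb_cfg["a0"]), float(fb_cfg["a1"])))
        else:
            s_max = int(s_max_cfg)
        feedback = make_step_response(
            s_max, int(fb_cfg["s_thresh"]), float(fb_cfg["a0"]), float(fb_cfg["a1"])
        )

    return ModelSpec(burst=burst, feedback=feedback, s_max=s_max, epsilon=epsilon)


def load_config(path) -> ModelSpec:
    with open(Path(path)) as fh:
        cfg = yaml.safe_load(fh)
    return model_from_dict(cfg)


def model_to_dict(model: ModelSpec) -> dict:
    if model.burst.family_tag == "explicit":
        burst = {"pmf": model.burst.require_pmf().tolist()}
    else:
        burst = {"mean": model.burst.mean, "fano": model.burst.fano}
    fb = model.feedback
    if fb.s_thresh is not None:
        feedback = {"s_thresh": fb.s_thresh, "a0": fb.a0, "a1": fb.a1}
    else:
        feedback = {"rates": fb.rates.tolist()}
    return {
        "burst": burst,
        "feedback": feedback,
        "model": {"s_max": model.s_max, "epsilon": model.epsilon},
    }


def dump_config(model: ModelSpec, path) -> None:
    with open(Path(path), "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)
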