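"""Structured text configuration for the model.

The bundled ``data/default.yaml`` mirrors every printed model parameter of
the mossy-fiber pearl-chain model; :func:`build_chain` turns a config dict
into a :class:`~mossyfiber.geometry.CompartmentChain`, and
:func:`save_config`/:func:`load_config` round-trip configs through YAML.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .geometry import CompartmentChain, PassiveParams, build_mossy_fiber_model

__all__ = ["default_config", "load_config", "save_config", "build_chain"]


def default_config() -> dict:
    """The bundled configuration reproducing the default model verbatim."""
    text = resources.files("mossyfiber").joinpath("data/default.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path) -> dict:
    """Load a model configuration from a YAML file."""
    return yaml.safe_load(Path(path).read_text())


def save_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def build_chain(cfg: dict | None = None) -> CompartmentChain:
    """Build a compartment chain from a configuration dict."""
    cfg = cfg or default_config()
    geo = cfg.get("geometry", {})
    pas = cfg.get("passive", {})
    chan = cfg.get("channels", {})
    gating = cfg.get("gating", {})
    return build_mossy_fiber_model(
        n_boutons=geo.get("n_boutons", 10),
        soma_diameter=geo.get("soma_diameter", 10.0),
        axon_diameter=geo.get("axon_diameter", 0.2),
        axon_length=geo.get("axon_length", 100.0),
        bouton_diameter=geo.get("bouton_diameter", 4.0),
        nseg_per_um=geo.get("nseg_per_um", 1.0),
        passive=PassiveParams(
            cm=pas.get("cm", 1.0),
            rm=pas.get("rm", 10_000.0),
            ri=pas.get("ri", 110.0),
            e_leak=pas.get("e_leak", -81.0),
        ),
        gna_axon=chan.get("gna_axon", 50.0),
        gna_soma=chan.get("gna_soma", 10.0),
        gk=chan.get("gk", 36.0),
        e_na=chan.get("e_na", 50.0),
        e_k=chan.get("e_k", -85.0),
        gating_model_id=gating.get("model", "hh_shifted"),
        gating_params=gating.get("params", {}) or {},
    )
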