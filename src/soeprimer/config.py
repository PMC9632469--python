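"""Config-file loading: YAML (nested or dotted flat keys) or ``key=value`` lines.

Recognized keys (dotted form):

* ``design.tm_favorite``, ``design.end_len_min``, ``design.end_len_max``,
  ``design.offset_min``, ``design.offset_max``, ``design.fwd_frag1_base``,
  ``design.fwd_frag2_base``, ``design.rev_frag1_base``, ``design.rev_frag2_base``
* ``thermo.monovalent_mM``, ``thermo.primer_nM``, ``thermo.divalent_mM``,
  ``thermo.dntp_mM``, ``thermo.salt_correction``, ``thermo.nn_table``,
  ``thermo.method``
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .design import DesignConfig
from .errors import ConfigError
from .thermo import ThermoConditions

_THERMO_KEYS = {
    "monovalent_mM": "monovalent_cation_mM",
    "primer_nM": "primer_concentration_nM",
    "divalent_mM": "divalent_cation_mM",
    "dntp_mM": "dNTP_mM",
    "salt_correction": "salt_correction",
    "nn_table": "nn_table",
    "method": "method",
}
_DESIGN_KEYS = {f.name: f.name for f in DesignConfig.__dataclass_fields__.values()}


def _flatten(prefix: str, node, out: dict) -> None:
    if isinstance(node, dict):
        for key, val in node.items():
            _flatten(f"{prefix}{key}.", val, out)
    else:
        out[prefix[:-1]] = node


def _parse_flat(text: str) -> dict:
    out = {}
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"cannot parse config line: {raw!r}")
        key, _, val = line.partition("=")
        out[key.strip()] = yaml.safe_load(val.strip())
    return out


def load_config(path: str | Path) -> tuple[DesignConfig, ThermoConditions]:
    """Read a config file into (DesignConfig, ThermoConditions)."""
    text = Path(path).read_text()
    parsed = yaml.safe_load(text)
    flat: dict = {}
    if isinstance(parsed, dict):
        _flatten("", parsed, flat)
    elif parsed is None:
        pass
    else:  # a plain key=value file parses as a YAML scalar
        flat = _parse_flat(text)

    design_kwargs, thermo_kwargs = {}, {}
    for key, val in flat.items():
        section, _, name = key.partition(".")
        if section == "design" and name in _DESIGN_KEYS:
            design_kwargs[_DESIGN_KEYS[name]] = val
        elif section == "thermo" and name in _THERMO_KEYS:
            thermo_kwargs[_THERMO_KEYS[name]] = val
        else:
            raise ConfigError(f"unknown config key: {key}")
    return DesignConfig(**design_kwargs), ThermoConditions(**thermo_kwargs)
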