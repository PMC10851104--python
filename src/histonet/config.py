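"""Default thresholds and bundled configuration tables.

All of the pipeline's numeric thresholds live here so that they are
defaults, not literals scattered through the code: the 5 Å heavy-atom
contact cutoff, the MCC >= 4 hub rule, the tumor-mutation-burden and
recurrence filters for the refined mutation set, the ddG disruption
thresholds per interaction class, and the interface-Jaccard redundancy
knob used during representative selection.
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from histonet.exceptions import ConfigurationError

#: Pipeline-wide defaults (units in comments).
DEFAULTS: dict[str, Any] = {
    "contact_cutoff": 5.0,          # Å, inclusive, heavy atoms only
    "mcc_hub_threshold": 4,         # MCC score >= 4 -> hub
    "tmb_cutoff": 10.0,             # mutations/Mb, strict > drops the sample
    "recurrence_min": 3,            # distinct samples for a recurrent mutation
    "ddg_thresholds": {             # kcal/mol, mean ddG >= threshold -> disruptive
        "HDI": 1.0,
        "HHI": 1.5,
        "HPI": 1.5,
    },
    "redundancy_jaccard": 0.8,      # interface-residue Jaccard for redundancy
    "min_core_histones": 7,         # of 8 core-histone chains
    "max_unanchored_bp": 20,        # bp of DNA allowed to lose octamer contact
    "min_partner_length": 10,       # residues
    "callable_mb": 38.0,            # exome territory for TMB derivation
    "identity_threshold": 0.6,      # histone sequence-identity fallback
    "strand_pair_tolerance": 4,     # nt length mismatch tolerated when pairing
}


def _read_packaged_yaml(name: str) -> Any:
    ref = resources.files("histonet.data").joinpath(name)
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def load_histone_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load the histone keyword/reference-sequence table.

    Returns a dict with keys ``identity_threshold`` and ``types`` where
    ``types`` maps H1/H2A/H2B/H3/H4 to ``{"keywords": [...], "reference": str}``.
    Reference sequences are whitespace-stripped to plain uppercase strings.
    """
    if path is None:
        cfg = _read_packaged_yaml("histone_config.yaml")
    else:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    if not cfg or not cfg.get("types"):
        raise ConfigurationError("histone config has no 'types' entries")
    cfg = copy.deepcopy(cfg)
    for htype, entry in cfg["types"].items():
        if not entry.get("keywords"):
            raise ConfigurationError(f"histone type {htype} has no keywords")
        ref = entry.get("reference") or ""
        entry["reference"] = "".join(ref.split()).upper()
    cfg.setdefault("identity_threshold", DEFAULTS["identity_threshold"])
    return cfg


def load_ptm_map(path: str | Path | None = None) -> dict[str, str]:
    """Load the chemical-component -> PTM-type map (e.g. ALY -> lysine-acetylation)."""
    if path is None:
        raw = _read_packaged_yaml("ptm_map.yaml")
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    if not raw:
        raise ConfigurationError("PTM map is empty")
    return {str(k).upper(): str(v) for k, v in raw.items()}


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Merged pipeline configuration: DEFAULTS overridden by a YAML file."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    return cfg
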