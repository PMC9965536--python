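"""Packaged, read-only records of the published in-paper datasets.

Every input the analysis needs is printed in the source publication;
those tables are transcribed here at their printed significant figures
(no re-derived values) and shipped as plain CSV/YAML under
``pbbm/data``.  Each file's SHA-256 is pinned in ``manifest.json`` and
verified on load.
"""

from __future__ import annotations

import hashlib
import json
from functools import lru_cache
from importlib import resources

import pandas as pd
import yaml

__all__ = ["fixture", "load_fixtures", "fixture_names", "FixtureIntegrityError"]

_FILES = {
    "table2": "table2_media.csv",
    "table4": "table4_permeability.csv",
    "table5": "table5_iv.csv",
    "table6": "table6_solubility.csv",
    "table7": "table7_logkmw.csv",
    "table8": "table8_pk.csv",
    "calibration_media": "calibration_media.csv",
    "solubility_screen": "solubility_screen.csv",
    "compound_model": "compound_model.yaml",
}


class FixtureIntegrityError(RuntimeError):
    """Packaged data file does not match its pinned checksum."""


def _data_root():
    return resources.files("pbbm") / "data"


@lru_cache(maxsize=1)
def _manifest() -> dict:
    with (_data_root() / "manifest.json").open("r") as fh:
        return json.load(fh)


def _read_verified(filename: str) -> bytes:
    raw = (_data_root() / filename).read_bytes()
    expected = _manifest().get(filename)
    if expected is None:
        raise FixtureIntegrityError(f"{filename} missing from manifest")
    digest = hashlib.sha256(raw).hexdigest()
    if digest != expected:
        raise FixtureIntegrityError(
            f"checksum mismatch for {filename}: {digest} != {expected}"
        )
    return raw


def fixture_names() -> list[str]:
    return sorted(_FILES)


@lru_cache(maxsize=None)
def fixture(name: str):
    """Load one named fixture (DataFrame, or dict for YAML files).

    Each returned table carries a ``source_table`` attribute naming its
    table of origin.
    """
    if name not in _FILES:
        raise KeyError(f"unknown fixture '{name}'; choose from {fixture_names()}")
    filename = _FILES[name]
    raw = _read_verified(filename)
    if filename.endswith(".yaml"):
        return yaml.safe_load(raw.decode())
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw))
    df.attrs["source_table"] = name
    return df


def load_fixtures() -> dict:
    """All packaged fixtures keyed by name."""
    return {name: fixture(name) for name in _FILES}
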