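"""Named instrument fixtures (TOML) shipped with the package."""

from __future__ import annotations

import tomllib
from importlib import resources


def load_fixture(name: str) -> dict:
    """Load a named fixture file, e.g. ``load_fixture('dof_replication')``."""
    ref = resources.files(__package__).joinpath(f"{name}.toml")
    with ref.open("rb") as fh:
        return tomllib.load(fh)
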