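"""Bundled example networks.

The p53-MDM2 negative-feedback loop is shipped in two variants, one per
constant value of the DNA double-strand-break input signal ``dna_dsb``:

* ``p53net_DNAdsb0`` — no stress; the all-zero state (every protein
  inactive) is the fixed point the system settles into.
* ``p53net_DNAdsb1`` — DNA damage; ATM inhibition of MDM2 releases p53 and
  the dynamics settle into a sustained oscillation of p53 activity.

Gene order: ATM, p53, WIP1, MDM2.
"""

from __future__ import annotations

from importlib import resources

from .network import BooleanNetwork, parse_boolnet

__all__ = ["available_networks", "load_example_network"]

_FILES = {
    "p53net_DNAdsb0": "p53net_DNAdsb0.txt",
    "p53net_DNAdsb1": "p53net_DNAdsb1.txt",
}


def available_networks() -> list[str]:
    return sorted(_FILES)


def load_example_network(name: str) -> BooleanNetwork:
    """Load a bundled network by name (see :func:`available_networks`)."""
    if name not in _FILES:
        raise KeyError(f"unknown example network {name!r}; available: {', '.join(sorted(_FILES))}")
    text = resources.files("pobds.data").joinpath(_FILES[name]).read_text(encoding="utf-8")
    return parse_boolnet(text)
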