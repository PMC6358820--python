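"""Packaged example networks.

``two_drug_toy`` is the canonical two-drug teaching example: drugs X and Y,
biological functions A–E, reactions 1–6.  X may perturb A, B and C; Y
may perturb C, D and E; A may manifest reactions 1–3, B and D reaction
5, C reaction 4, and E reaction 6.  Under the combination {X, Y},
reaction 4 is composite through the shared function C (mode 1) and
reaction 5 through the drug-specific functions B and D (mode 2).
"""

from importlib import resources
from pathlib import Path

from ..graph import TripartiteNetwork, read_gml

__all__ = ["two_drug_toy", "two_drug_toy_path"]


def two_drug_toy_path() -> Path:
    """Filesystem path of the packaged toy GML."""
    return Path(resources.files(__package__) / "two_drug_toy.gml")


def two_drug_toy() -> TripartiteNetwork:
    """Load the packaged two-drug toy network (13 nodes, 13 edges)."""
    return read_gml(two_drug_toy_path())
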