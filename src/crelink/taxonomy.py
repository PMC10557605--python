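"""Cell-type taxonomy: the mapping from cell types to broad categories.

The default taxonomy models a human lung atlas with 23 cell types grouped
into 4 categories: 8 epithelial, 7 immune, 4 endothelial, 4 stromal.
"""

from __future__ import annotations

from collections import Counter
from typing import Dict, List


DEFAULT_TAXONOMY: Dict[str, str] = {
    # epithelial (8)
    "AT2": "epithelial",
    "AT1": "epithelial",
    "club": "epithelial",
    "ciliated": "epithelial",
    "goblet": "epithelial",
    "basal": "epithelial",
    "AT1/AT2": "epithelial",
    "AT2-proliferating": "epithelial",
    # immune (7)
    "NK": "immune",
    "T": "immune",
    "macrophage": "immune",
    "monocyte": "immune",
    "B": "immune",
    "dendritic": "immune",
    "NK/T": "immune",
    # endothelial (4)
    "lymphatic": "endothelial",
    "artery": "endothelial",
    "vein": "endothelial",
    "capillary": "endothelial",
    # stromal (4)
    "fibroblast": "stromal",
    "smooth-muscle": "stromal",
    "mesothelial": "stromal",
    "myofibroblast": "stromal",
}


class TaxonomyError(ValueError):
    """Raised for unknown cell types or degenerate (empty) categories."""


def category_sizes(taxonomy: Dict[str, str]) -> Dict[str, int]:
    """Number of cell types per category."""
    sizes = Counter(taxonomy.values())
    if any(v == 0 for v in sizes.values()) or not sizes:
        raise TaxonomyError("taxonomy has an empty category")
    return dict(sizes)


def cell_types(taxonomy: Dict[str, str]) -> List[str]:
    return list(taxonomy)


def validate_taxonomy(taxonomy: Dict[str, str]) -> None:
    if not taxonomy:
        raise TaxonomyError("taxonomy is empty")
    category_sizes(taxonomy)
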