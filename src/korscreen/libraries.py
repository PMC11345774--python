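"""Accounting for the screened vendor libraries.

The campaign screened three natural-product (NP) collections and four
synthetic Enamine collections, about 3 million molecules in total. The
published counts are bundled here as inputs so the composition shares can
be recomputed from them rather than quoted.
"""

from __future__ import annotations

SCREENED_LIBRARIES: dict[str, dict] = {
    "NATx (Analyticon)": {"count": 33_717, "natural_product": True},
    "MEGx (Analyticon)": {"count": 6_541, "natural_product": True},
    "Natural product library (Selleckchem)": {"count": 2_724, "natural_product": True},
    "Advanced Collection (Enamine)": {"count": 640_219, "natural_product": False},
    "Functional Collection (Enamine)": {"count": 119_088, "natural_product": False},
    "HTS Collection (Enamine)": {"count": 2_146_100, "natural_product": False},
    "Premium Collection (Enamine)": {"count": 41_281, "natural_product": False},
}


def total_molecules(libraries: dict[str, dict] = SCREENED_LIBRARIES) -> int:
    return sum(v["count"] for v in libraries.values())


def natural_product_share(libraries: dict[str, dict] = SCREENED_LIBRARIES) -> float:
    """Natural-product share of the screened universe, in percent."""
    np_count = sum(v["count"] for v in libraries.values() if v["natural_product"])
    return 100.0 * np_count / total_molecules(libraries)


def synthetic_share(libraries: dict[str, dict] = SCREENED_LIBRARIES) -> float:
    """Synthetic-compound share in percent (complement of the NP share,
    computed from the counts themselves)."""
    return 100.0 - natural_product_share(libraries)
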