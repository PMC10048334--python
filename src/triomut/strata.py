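"""Genome stratification shared across the pipeline.

Sites are stratified along two axes: the reference base class (A/T vs C/G)
and the genomic region (gene vs intergenic). The four cells of that cross
are encoded as small integer codes so that per-stratum tallies reduce to
``np.bincount`` calls on large arrays.
"""

from __future__ import annotations

import numpy as np

#: Nucleotide alphabet used for integer-coded sequences (0=A, 1=C, 2=G, 3=T).
BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT_CODE = np.array([3, 2, 1, 0], dtype=np.uint8)
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

BASE_CLASSES = ("AT", "CG")
REGIONS = ("intergenic", "gene")

#: Stratum labels indexed by code ``base_class + 2 * is_gene``.
STRATA = (
    "intergenic:AT",
    "intergenic:CG",
    "gene:AT",
    "gene:CG",
)
N_STRATA = len(STRATA)


def base_to_code(base: str) -> int:
    try:
        return _BASE_TO_CODE[base.upper()]
    except KeyError:
        raise ValueError(f"unsupported base {base!r}; expected one of {BASES}")


def code_to_base(code: int) -> str:
    return BASES[code]


def complement_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT_CODE[codes]


def base_class_of(base: str) -> str:
    """Return ``"AT"`` or ``"CG"`` for a reference base."""
    code = base_to_code(base)
    return "CG" if code in (1, 2) else "AT"


def stratum_code(region: str, base_class: str) -> int:
    if region not in REGIONS:
        raise ValueError(f"unknown region {region!r}")
    if base_class not in BASE_CLASSES:
        raise ValueError(f"unknown base class {base_class!r}")
    return BASE_CLASSES.index(base_class) + 2 * REGIONS.index(region)


def stratum_label(code: int) -> str:
    return STRATA[code]


def split_stratum(label: str) -> tuple[str, str]:
    """Split ``"gene:AT"`` into ``("gene", "AT")``."""
    region, base_class = label.split(":")
    return region, base_class


def stratum_codes(ref_codes: np.ndarray, gene_mask: np.ndarray) -> np.ndarray:
    """Per-site stratum codes from integer-coded reference and a gene mask.

    Parameters
    ----------
    ref_codes
        ``uint8`` array of reference base codes (0=A, 1=C, 2=G, 3=T).
    gene_mask
        Boolean array, True where the site lies in an annotated gene.
    """
    is_cg = (ref_codes == 1) | (ref_codes == 2)
    return (is_cg.astype(np.uint8) + 2 * gene_mask.astype(np.uint8))
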