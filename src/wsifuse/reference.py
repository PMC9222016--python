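"""Reference dimensions and benchmark-cohort composition tables.

The descriptor dimensions fix the architecture: a same-size dense encoder
per descriptor and the fused latent width their concatenation.  The patch
cohort tables record the per-class patch counts of the two public WSI
benchmarks commonly used for breast (ICIAR2018, 20x, four classes) and
lung adenocarcinoma (DHMC/Dartmouth, 20x, five subtypes) patch
classification; they drive dataset-size accounting such as class
balancing (the invasive breast class is subsampled to 3,800 patches in
the balanced variant).
"""

from __future__ import annotations

DESCRIPTOR_DIMS: dict[str, int] = {"raw": 4800, "hog": 64, "lbp": 254}

FUSED_DIM: int = sum(DESCRIPTOR_DIMS.values())  # 5118

HEAD_WIDTHS: tuple[int, int] = (1024, 512)

# ICIAR2018 breast-histology patch cohort (20x), per-class patch counts.
BREAST_PATCH_COUNTS: dict[str, dict[str, int]] = {
    "unbalanced": {
        "benign": 3770,
        "normal": 1200,
        "in_situ": 1655,
        "invasive": 25590,
    },
    "balanced": {
        "benign": 3770,
        "normal": 1200,
        "in_situ": 1655,
        "invasive": 3800,  # invasive subsampled for balance
    },
}

# Dartmouth (DHMC) lung adenocarcinoma patch cohort (31 WSIs, 20x).
LUNG_PATCH_COUNTS: dict[str, int] = {
    "acinar": 38611,
    "lepidic": 39092,
    "micropapillary": 40349,
    "papillary": 32228,
    "solid": 38190,
}

LUNG_WSI_COUNTS: dict[str, int] = {
    "acinar": 9,
    "lepidic": 5,
    "micropapillary": 5,
    "papillary": 4,
    "solid": 8,
}


def cohort_total(counts: dict[str, int]) -> int:
    """Total patch count of a cohort table."""
    return sum(counts.values())
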