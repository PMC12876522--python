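"""Published summary statistics of the combined four-dataset chest X-ray corpus.

The toolkit's partitioning and bookkeeping operations are validated against the
label-instance census of the combined CheXpert / MIMIC-CXR-JPG / ChestX-ray14 /
PadChest corpus (479,215 images after the age and completeness filters).  The
census is small — 15 pathologies by 4 sources — so it is committed verbatim
here rather than re-derived from the original datasets, which this package
never downloads.

Counts are label *instances* (an image with two pathologies contributes two),
not images.  A missing (class, source) cell means the source provides no
images for that pathology; it is stored as 0.
"""

from __future__ import annotations

import pandas as pd

#: Canonical pathology names, in the corpus' conventional order.
PATHOLOGIES: tuple[str, ...] = (
    "Effusion",
    "Lung opacity",
    "Atelectasis",
    "Infiltration",
    "Nodule",
    "Mass",
    "Pleural thickening",
    "Emphysema",
    "Fibrosis",
    "Hernia",
    "Cardiomegaly",
    "Edema",
    "Pneumothorax",
    "Consolidation",
    "Pneumonia",
)

#: Source-dataset tags.
SOURCES: tuple[str, ...] = ("CheXpert", "MIMIC", "ChestX-ray14", "PadChest")

_COUNTS = {
    #                     CheXpert   MIMIC  ChestX-ray14  PadChest
    "Effusion":           (66_484, 43_544, 13_086, 5_075),
    "Lung opacity":       (77_194, 42_779,      0,     0),
    "Atelectasis":        (25_980, 38_297, 11_335, 4_808),
    "Infiltration":       (     0,      0, 19_362, 10_455),
    "Nodule":             (     0,      0,  6_238, 3_429),
    "Mass":               (     0,      0,  5_682,   738),
    "Pleural thickening": (     0,      0,  3_326, 2_691),
    "Emphysema":          (     0,      0,  2_484,   939),
    "Fibrosis":           (     0,      0,  1_650,   489),
    "Hernia":             (     0,      0,    197, 1_034),
    "Cardiomegaly":       (20_391, 36_512,  2_701, 6_782),
    "Edema":              (41_247, 21_894,  2_269,   865),
    "Pneumothorax":       (14_977,  9_215,  5_220,   306),
    "Consolidation":      (10_340,  9_183,  4_505, 1_197),
    "Pneumonia":          ( 2_986, 13_679,  1_381, 3_548),
}

#: Not-finding (all-negative) image counts of the published meta-partition,
#: keyed by meta-set.
REFERENCE_NORMALS: dict[str, int] = {"trn": 99_983, "val": 1_788, "tst": 54_969}

#: Number of images carrying at least one pathology label in the combined
#: corpus.  Together with the instance census this determines the label
#: cardinality (596,494 / 322,475 ≈ 1.85).
REFERENCE_N_LABELED: int = 322_475

#: Total number of images in the combined corpus (labeled + not finding).
REFERENCE_N_IMAGES: int = REFERENCE_N_LABELED + sum(REFERENCE_NORMALS.values())


def reference_class_source_counts() -> pd.DataFrame:
    """Per-class per-source label-instance counts of the combined corpus.

    Returns a 15 x 4 integer DataFrame indexed by pathology name with one
    column per source tag.  Row sums give the global per-class counts; the
    grand total is 596,494 instances.
    """
    frame = pd.DataFrame.from_dict(_COUNTS, orient="index", columns=list(SOURCES))
    frame.index.name = "class"
    return frame.loc[list(PATHOLOGIES)].astype(int)


def reference_counts() -> tuple[pd.DataFrame, dict[str, int]]:
    """The class/source census together with the per-meta-set normal counts."""
    return reference_class_source_counts(), dict(REFERENCE_NORMALS)
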