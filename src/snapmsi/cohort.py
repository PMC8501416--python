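"""Bookkeeping of the pilot-study acquisition log the analysis targets.

The clinical campaign this package's synthetic generator emulates acquired
multispectral image cubes from cautery-marked esophageal regions, each
matched with a histopathological diagnosis.  The per-region acquisition log
(trial number, location, diagnosis, matched cube count) ships with the
package as ``data/cohort_regions.csv``; this module derives the study-level
totals from it — region counts per tissue class, matched cube totals, and
the train/test cube counts implied by the cube-level 80/20 split.

The neoplasia class pools low-grade dysplasia (LGD), high-grade dysplasia
(HGD) and intramucosal carcinoma (IMC).  One region without a confirming
biopsy ("NA") was analyzed as NDBE.  Squamous control cubes were acquired
separately from the matched-region log: 157 cubes from 9 regions.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

#: squamous control acquisitions, recorded outside the matched-region log
SQUAMOUS_REGIONS = 9
SQUAMOUS_CUBES = 157

#: diagnoses pooled into the neoplasia class
NEOPLASTIC_DIAGNOSES = ("LGD", "HGD", "IMC")


def load_matched_regions() -> pd.DataFrame:
    """The per-region acquisition log of matched (biopsy-confirmed) regions."""
    with resources.files("snapmsi.data").joinpath("cohort_regions.csv").open() as fh:
        return pd.read_csv(fh, keep_default_na=False)


def class_of_diagnosis(diagnosis: str) -> str:
    """Map a histopathological diagnosis to its analysis class.

    LGD/HGD/IMC pool into neoplasia; NDBE stays NDBE; the unconfirmed "NA"
    region was analyzed as NDBE.
    """
    d = str(diagnosis).strip().upper()
    if d in NEOPLASTIC_DIAGNOSES:
        return "neoplasia"
    if d in ("NDBE", "NA"):
        return "ndbe"
    raise ValueError(f"unknown diagnosis {diagnosis!r}")


def cohort_summary(regions: pd.DataFrame | None = None) -> dict:
    """Study-level totals derived from the acquisition log."""
    df = load_matched_regions() if regions is None else regions
    classes = df["diagnosis"].map(class_of_diagnosis)
    n_ndbe_regions = int((classes == "ndbe").sum())
    n_neo_regions = int((classes == "neoplasia").sum())
    matched = int(df["n_cubes"].sum())
    return {
        "matched_regions": len(df),
        "ndbe_regions": n_ndbe_regions,
        "neoplasia_regions": n_neo_regions,
        "matched_cubes": matched,
        "ndbe_cubes": int(df.loc[classes == "ndbe", "n_cubes"].sum()),
        "neoplasia_cubes": int(df.loc[classes == "neoplasia", "n_cubes"].sum()),
        "squamous_regions": SQUAMOUS_REGIONS,
        "squamous_cubes": SQUAMOUS_CUBES,
        "total_cubes": matched + SQUAMOUS_CUBES,
    }


def split_counts(n_cubes: int, train_fraction: float = 0.8) -> tuple[int, int]:
    """Train/test cube counts of the cube-level split: floor(0.8 N) for
    training, the remainder for testing."""
    n_train = int(np.floor(train_fraction * n_cubes))
    return n_train, n_cubes - n_train
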