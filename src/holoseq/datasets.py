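"""Sample metadata and dataset subsetting for the coral study design.

The bundled metadata describes the 27-sample *Montipora capitata*
RNA-seq design this pipeline targets: two Hawai'i Island field sites
(Wai'opae, windward tidepools; Kiholo, leeward bay), per-sample
dominant *Symbiodinium* clade from ITS2 read proportions (C, D, or a
mixed composition), and Growth Anomaly (GA) disease status, with
lesioned ("ga_affected") and morphologically unaffected
("ga_unaffected") tissue pairs sharing a colony.

Analyses run on named subsets:

* ``all``      - every sample;
* ``default``  - all minus outliers: an expression-clustering outlier
  (config-supplied; WA8 in the bundled design) and samples whose ITS2
  composition reaches 0.25 for more than one clade;
* ``waiopae``  - Wai'opae samples only, outliers removed;
* ``hu``       - healthy + GA-unaffected tissue only, outliers removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import pandas as pd

# sample, colony, site, clade-C proportion, clade-D proportion, GA status.
# Proportions of 1/0 mean only one clade was detected.
_STUDY_TSV = """\
sample_id\tcolony_id\tsite\tprop_C\tprop_D\tga_status
KH1\tKH1\tkiholo\t0\t1\thealthy
KH2\tKH2\tkiholo\t0\t1\thealthy
KH8\tKH8\tkiholo\t0\t1\thealthy
KU2\tK2\tkiholo\t1\t0\tga_unaffected
KU3\tK3\tkiholo\t0\t1\tga_unaffected
KU5\tK5\tkiholo\t0\t1\tga_unaffected
KA2\tK2\tkiholo\t1\t0\tga_affected
KA3\tK3\tkiholo\t0\t1\tga_affected
KA5\tK5\tkiholo\t0\t1\tga_affected
WH1\tWH1\twaiopae\t1\t0\thealthy
WH2\tWH2\twaiopae\t0\t1\thealthy
WH3\tWH3\twaiopae\t1\t0\thealthy
WH5\tWH5\twaiopae\t0\t1\thealthy
WH8\tWH8\twaiopae\t0.33\t0.67\thealthy
WH12\tWH12\twaiopae\t0\t1\thealthy
WU1\tW1\twaiopae\t1\t0\tga_unaffected
WU2\tW2\twaiopae\t1\t0\tga_unaffected
WU3\tW3\twaiopae\t0\t1\tga_unaffected
WU5\tW5\twaiopae\t1\t0\tga_unaffected
WU8\tW8\twaiopae\t1\t0\tga_unaffected
WU12\tW12\twaiopae\t0.09\t0.91\tga_unaffected
WA1\tW1\twaiopae\t0.88\t0.12\tga_affected
WA2\tW2\twaiopae\t1\t0\tga_affected
WA3\tW3\twaiopae\t0.13\t0.87\tga_affected
WA5\tW5\twaiopae\t1\t0\tga_affected
WA8\tW8\twaiopae\t1\t0\tga_affected
WA12\tW12\twaiopae\t0.38\t0.62\tga_affected
"""

#: clustering-based expression outlier in the bundled design (flag-only
#: elsewhere; excluded from the 'default' subset by explicit listing)
CLUSTERING_OUTLIERS = ("WA8",)

MIXED_THRESHOLD = 0.25


def load_study_design() -> pd.DataFrame:
    """The bundled 27-sample metadata with derived clade columns.

    Adds ``clade`` (dominant clade) and ``mixed`` (True when two or more
    clades each reach the 0.25 proportion threshold).
    """
    df = pd.read_csv(StringIO(_STUDY_TSV), sep="\t").set_index("sample_id")
    df["clade"] = (df["prop_D"] > df["prop_C"]).map({True: "D", False: "C"})
    df["mixed"] = (df[["prop_C", "prop_D"]] >= MIXED_THRESHOLD).sum(axis=1) >= 2
    return df


@dataclass
class DatasetSpec:
    name: str
    excluded: tuple = ()
    samples: list = field(default_factory=list)


def build_datasets(metadata: pd.DataFrame,
                   clustering_outliers=CLUSTERING_OUTLIERS) -> dict:
    """Derive the four named sample subsets from metadata.

    ``metadata`` needs columns site, ga_status and mixed (or prop_C /
    prop_D from which mixed is derived).  Unknown samples in the
    clustering-outlier list raise.
    """
    md = metadata.copy()
    if "mixed" not in md.columns:
        md["mixed"] = (md[["prop_C", "prop_D"]] >= MIXED_THRESHOLD).sum(axis=1) >= 2
    unknown = set(clustering_outliers) - set(md.index)
    if unknown:
        raise KeyError(f"unknown samples in exclusion list: {sorted(unknown)}")
    mixed = set(md.index[md["mixed"]])
    excluded = mixed | set(clustering_outliers)
    default = [s for s in md.index if s not in excluded]
    out = {
        "all": DatasetSpec("all", (), list(md.index)),
        "default": DatasetSpec("default", tuple(sorted(excluded)), default),
        "waiopae": DatasetSpec(
            "waiopae", tuple(sorted(excluded)),
            [s for s in default if md.loc[s, "site"] == "waiopae"]),
        "hu": DatasetSpec(
            "hu", tuple(sorted(excluded)),
            [s for s in default if md.loc[s, "ga_status"] != "ga_affected"]),
    }
    return out


def colony_table(metadata: pd.DataFrame) -> pd.DataFrame:
    """One row per colony with site, dominant clade and disease state."""
    md = metadata.copy()
    rows = []
    for colony, grp in md.groupby("colony_id", sort=False):
        site = grp["site"].iloc[0]
        # dominant clade from pooled proportions across the colony's samples
        clade = "D" if grp["prop_D"].mean() > grp["prop_C"].mean() else "C"
        diseased = (grp["ga_status"] != "healthy").any()
        rows.append((colony, site, clade, "diseased" if diseased else "healthy"))
    return pd.DataFrame(rows, columns=["colony_id", "site", "clade", "health"]
                        ).set_index("colony_id")


def contingency_tables(metadata: pd.DataFrame) -> dict:
    """Colony-level 2x2 tables: site x clade and health x clade.

    Rows/columns ordered as ((waiopae, kiholo) x (C, D)) and
    ((healthy, diseased) x (C, D)).
    """
    col = colony_table(metadata)

    def count(sel, clade):
        return int(((sel) & (col["clade"] == clade)).sum())

    site_tbl = [[count(col["site"] == "waiopae", "C"), count(col["site"] == "waiopae", "D")],
                [count(col["site"] == "kiholo", "C"), count(col["site"] == "kiholo", "D")]]
    ga_tbl = [[count(col["health"] == "healthy", "C"), count(col["health"] == "healthy", "D")],
              [count(col["health"] == "diseased", "C"), count(col["health"] == "diseased", "D")]]
    return {"site_by_clade": site_tbl, "health_by_clade": ga_tbl}
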