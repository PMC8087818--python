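"""Published TACC2 p10 amplicon exon catalog, shipped as package data.

The 29 representative exon regions (rex01..rex29) and 21 boundary variants
reported for isoforms transcribed from the intronic p10 promoter of human
TACC2 (GRCh37 chr10). Lengths, symmetry and variant arithmetic are *not*
stored; they are recomputed from the coordinates and pattern strings, so the
printed flags in the variant table serve as an independent cross-check.
"""

from __future__ import annotations

import importlib.resources
from typing import List

import pandas as pd

from .exons import ExonCatalog, ExonVariant, RepresentativeExon, apply_pattern
from .model import GenomeInterval


def _data(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("isoscope.data").joinpath(name)
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_published_exons() -> pd.DataFrame:
    """The published exon table: name, label, coordinates, state, annotation."""
    return _data("tacc2_p10_exons.tsv")


def load_published_variants() -> pd.DataFrame:
    """The published boundary-variant table with its printed flags."""
    return _data("tacc2_p10_variants.tsv")


def published_catalog() -> ExonCatalog:
    """The published catalog as an ExonCatalog with variant intervals
    reconstructed by applying each pattern to its parent's boundaries."""
    exons = load_published_exons()
    reps: List[RepresentativeExon] = []
    for _, row in exons.iterrows():
        reps.append(
            RepresentativeExon(
                rex_id=row["name"],
                interval=GenomeInterval(row["chrom"], int(row["start"]), int(row["end"])),
                state=row["state"],
                annotation=row["annotation"],
            )
        )
    catalog = ExonCatalog(representatives=reps)
    variants: List[ExonVariant] = []
    counters: dict = {}
    for _, row in load_published_variants().iterrows():
        parent = catalog.representative(row["parent"])
        iv = apply_pattern(parent.interval, row["pattern"])
        counters[row["parent"]] = counters.get(row["parent"], 0) + 1
        variants.append(
            ExonVariant(
                parent=row["parent"],
                interval=iv,
                pattern=row["pattern"],
                shares_boundary=(iv.start == parent.interval.start)
                or (iv.end == parent.interval.end),
                variant_id=f"{row['parent']}.v{counters[row['parent']]}",
            )
        )
    catalog.variants = variants
    return catalog
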