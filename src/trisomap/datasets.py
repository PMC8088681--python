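"""Bundled reference datasets.

The two validation tables are the published gene panels of the trisomy-21
blood-cell study this pipeline targets: paired differential expression
ratios (trisomic over control) as derived from the RNA-seq transcriptome
map and as measured by real-time RT-PCR.  The first panel (19 genes) was
assayed on the same RNA samples used for sequencing; the second (6 genes,
including the GAPDH reference) re-assayed significantly over-expressed
genes on a larger independent cohort.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("trisomap.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chromosome": str, "gene": str})


def load_validation_ratios(cohort: str = "rnaseq") -> pd.DataFrame:
    """Load a bundled validation panel.

    cohort "rnaseq": the 19-gene panel assayed on the sequencing samples.
    cohort "extended": the 6-gene over-expression panel from the larger
    cohort.  Columns: chromosome, gene, ratio_map, ratio_qpcr.
    """
    files = {
        "rnaseq": "validation_ratios_rnaseq_cohort.tsv",
        "extended": "validation_ratios_extended_cohort.tsv",
    }
    if cohort not in files:
        raise ValueError(f"cohort must be one of {sorted(files)}")
    return _load(files[cohort])
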