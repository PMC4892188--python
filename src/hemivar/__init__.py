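"""hemivar: hemizygous-variant cataloging for 22q11-style microdeletion cohorts.

Pipeline stages: Phred-likelihood call classification and hemizygous
filtering, deletion typing from binned coverage and windowed zygosity
against an LCR map, cohort variant cataloging with rare-variant rules,
per-gene variant-burden regression with Studentized-residual outliers,
conservation averaging, and UPGMA platform clustering — plus a synthetic
cohort generator with known truth.
"""

from importlib import resources

__version__ = "0.1.0"


def data_path(name: str):
    """Path to a packaged data file (e.g. the cohort gene-variant tally)."""
    return resources.files("hemivar") / "data" / name


def load_cohort_counts() -> dict:
    """Headline bookkeeping counts of the emulated 127-patient cohort."""
    import json

    with data_path("cohort_counts.json").open() as fh:
        return json.load(fh)
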