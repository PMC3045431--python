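"""Bundled published tables from the Nicastrin pooled-sequencing screen.

Three small TSVs ship with the package:

* ``nicastrin_pool_sequencing.tsv`` — the variants nominated by pooled
  sequencing of 311 Alzheimer's cases and 360 controls: pool frequencies,
  depths and strand-balance (F:R ratio) scores per pool, plus the individual
  Sequenom genotyping frequencies where validation was carried out.  A pool
  frequency of 0 means the substitution was not seen in that pool (its
  strand-balance score is then missing).  ``below_cutoff`` marks the two
  variants genotyped despite failing the calling threshold.
* ``nicastrin_validated_genotypes.tsv`` — per-group genotype counts
  (individuals, minor-allele homozygotes, heterozygotes) for the validated
  variants, in the long format :func:`poolscreen.association.associate`
  consumes.
* ``n417y_replication_studies.tsv`` — the N417Y replication cohorts:
  per-study sample sizes, minor-allele frequencies and published odds
  ratios with 95% confidence intervals, as consumed by
  :func:`poolscreen.meta.dl_meta`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .meta import StudyEffect


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("poolscreen").joinpath("data", name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_pool_sequencing() -> pd.DataFrame:
    """Pool-sequencing variant nominations with validation genotyping."""
    return _read("nicastrin_pool_sequencing.tsv")


def load_validated_genotypes() -> pd.DataFrame:
    """Long-format genotype counts for the validated variants."""
    return _read("nicastrin_validated_genotypes.tsv")


def load_replication_studies() -> pd.DataFrame:
    """N417Y replication cohorts with published ORs and CIs."""
    return _read("n417y_replication_studies.tsv")


def replication_effects() -> list[StudyEffect]:
    """The replication cohorts as :class:`StudyEffect` objects."""
    df = load_replication_studies()
    return [
        StudyEffect(str(r["study"]), float(r["or"]), float(r["ci_lo"]), float(r["ci_hi"]))
        for _, r in df.iterrows()
    ]
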