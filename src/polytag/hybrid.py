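"""Sub-genome classification and dosage calling for interspecific hybrids.

In a wide cross between two species (here "cran" and "blue" parental
genomes), a targeted amplicon may amplify from one parental sub-genome,
from both, or from neither.  Parental read totals decide the class: a
locus with total Ref+Alt reads <= threshold summed across the blue-parent
samples and > threshold summed across the cran-parent samples is
cran-genome specific, and vice versa; > threshold in both is shared;
<= threshold in both is failed and excluded from genotyping.

Genome-specific loci are then dosage-called in the hybrids at ploidy 1
(presence/absence of the alternative allele on the single amplifying
sub-genome) and shared loci at ploidy 4, via the "norm" dosage model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dosage import GenotypeMatrix, fit_norm_model
from .madc import CountMatrix
from .qc import DEFAULT_MIN_READS

LABELS = ("cran_specific", "blue_specific", "shared", "failed")
DEFAULT_THRESHOLD = 10


def classify_loci(counts: CountMatrix, blue_parents, cran_parents,
                  threshold: int = DEFAULT_THRESHOLD,
                  rule: str = "sum") -> pd.DataFrame:
    """Classify every locus by parental amplification.

    rule="sum" compares the group-summed Ref+Alt totals B and C against the
    threshold; rule="each" instead requires every sample in the group to be
    on the same side of the threshold (the stricter per-sample reading).

    Returns a DataFrame indexed by locus with columns label, B, C.
    """
    for group, name in ((blue_parents, "blue"), (cran_parents, "cran")):
        if not group:
            raise ValueError(f"{name} parent group is empty")
        missing = [s for s in group if s not in counts.samples]
        if missing:
            raise ValueError(f"unknown parent sample(s): {missing}")
    tot = counts.total()
    if rule == "sum":
        B = tot[list(blue_parents)].sum(axis=1)
        C = tot[list(cran_parents)].sum(axis=1)
        blue_amp = B > threshold
        cran_amp = C > threshold
    elif rule == "each":
        B = tot[list(blue_parents)].sum(axis=1)
        C = tot[list(cran_parents)].sum(axis=1)
        blue_amp = (tot[list(blue_parents)] > threshold).all(axis=1)
        cran_amp = (tot[list(cran_parents)] > threshold).all(axis=1)
    else:
        raise ValueError("rule must be 'sum' or 'each'")
    label = np.where(cran_amp & blue_amp, "shared",
                     np.where(cran_amp, "cran_specific",
                              np.where(blue_amp, "blue_specific", "failed")))
    return pd.DataFrame({"label": label, "B": B, "C": C}, index=counts.loci)


def call_hybrid_dosages(counts: CountMatrix, classes: pd.DataFrame,
                        hybrid_samples, specific_ploidy: int = 1,
                        shared_ploidy: int = 4,
                        min_reads: int = DEFAULT_MIN_READS,
                        seed: int = 0) -> GenotypeMatrix:
    """Call hybrid dosages per locus class.

    Genome-specific loci are called at specific_ploidy (default 1: the
    amplifying sub-genome's allele is scored present/absent) and shared
    loci at shared_ploidy (default 4); failed loci are excluded entirely.
    """
    hybrids = list(hybrid_samples)
    sub = counts.subset(samples=hybrids)
    specific = classes.index[classes["label"].isin(
        ["cran_specific", "blue_specific"])]
    shared = classes.index[classes["label"] == "shared"]

    parts, fits = [], {}
    ploidy_rows = []
    if len(specific):
        f1, g1 = fit_norm_model(sub.subset(loci=specific), m=specific_ploidy,
                                min_reads=min_reads, seed=seed)
        parts.append(g1)
        fits.update(f1)
    if len(shared):
        f2, g2 = fit_norm_model(sub.subset(loci=shared), m=shared_ploidy,
                                min_reads=min_reads, seed=seed)
        parts.append(g2)
        fits.update(f2)
    if not parts:
        raise ValueError("no loci to genotype after excluding failed class")
    keep_order = [l for l in counts.loci if l in set(specific) | set(shared)]
    dosage = pd.concat([p.dosage for p in parts]).loc[keep_order]
    maxpost = pd.concat([p.max_posterior for p in parts]).loc[keep_order]
    ploidy = pd.Series(shared_ploidy, index=pd.Index(hybrids))
    return GenotypeMatrix(dosage=dosage, max_posterior=maxpost,
                          ploidy=ploidy, fits=fits)
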