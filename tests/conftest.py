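import warnings

import numpy as np
import pandas as pd
import pytest

from polytag.madc import CountMatrix, MarkerDef

# the dosage EM warns on rare non-convergence; tests assert behavior, not logs
warnings.filterwarnings("ignore", message=".*did not converge.*")


@pytest.fixture
def toy_sheet():
    return pd.DataFrame({
        "sample_id": ["s1", "s2", "s3"],
        "group": ["a", "a", "b"],
        "nominal_ploidy": [2, 2, 2],
        "parent1": ["", "", ""],
        "parent2": ["", "", ""],
    })


@pytest.fixture
def toy_madc(tmp_path, toy_sheet):
    """Two loci, three samples, one Other row (locus 1)."""
    text = (
        "AlleleID,CloneID,AlleleSequence,s1,s2,s3\n"
        "chr1_100|Ref,chr1_100,AAA,10,20,30\n"
        "chr1_100|Alt,chr1_100,AAT,5,15,25\n"
        "chr1_100|Other_1,chr1_100,AAC,1,2,3\n"
        "chr2_500|Ref,chr2_500,GGG,7,0,40\n"
        "chr2_500|Alt,chr2_500,GGC,3,9,60\n"
    )
    path = tmp_path / "toy.csv"
    path.write_text(text)
    return path


def make_counts(ref, alt, loci=None, samples=None) -> CountMatrix:
    ref = np.atleast_2d(ref)
    loci = loci or [f"m{i}" for i in range(ref.shape[0])]
    samples = samples or [f"s{j}" for j in range(ref.shape[1])]
    idx = pd.Index(loci, name="locus_id")
    return CountMatrix(pd.DataFrame(np.atleast_2d(ref), index=idx, columns=samples),
                       pd.DataFrame(np.atleast_2d(alt), index=idx, columns=samples))


def make_markers(positions, chrom="1"):
    return [MarkerDef(f"{chrom}_{p}_{i}", chrom=chrom, pos=p)
            for i, p in enumerate(positions)]
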