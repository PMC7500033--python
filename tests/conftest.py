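import numpy as np
import pytest

from mitodel import refmap
from mitodel.refmap import DeletionSpan
from mitodel.synth import PopulationSpec
import mitodel as M


@pytest.fixture(scope="session")
def ref():
    return refmap.default_reference()


@pytest.fixture(scope="session")
def fmap():
    return refmap.default_feature_map()


@pytest.fixture(scope="session")
def small_sample(ref, tmp_path_factory):
    """A small synthetic sample: one major-arc deletant at 10% plus one
    minor-arc deletant at 2%, 300x depth."""
    d = tmp_path_factory.mktemp("sample")
    species = [(DeletionSpan(8471, 13447), 0.10),
               (DeletionSpan(1000, 3500), 0.02)]
    spec = PopulationSpec(ref=ref, species=species, depth=300, seed=7)
    fq1, fq2 = d / "r1.fastq", d / "r2.fastq"
    truth = M.generate_reads(spec, fq1, fq2)
    return {"fq1": fq1, "fq2": fq2, "truth": truth, "species": species,
            "spec": spec}


@pytest.fixture(scope="session")
def small_catalog(ref, small_sample):
    return M.build_catalog(small_sample["fq1"], small_sample["fq2"], ref,
                           sample_id="small")


def make_catalog(rows, L=16571, r_t=100_000, L_r=150.0, min_anchor=20):
    """Hand-built catalog from (ls5, hs5, x_i[, wraps]) tuples."""
    import pandas as pd

    from mitodel.splitread import DeletionCatalog

    recs = []
    for row in rows:
        ls5, hs5, x = row[:3]
        wraps = row[3] if len(row) > 3 else False
        length = (hs5 - ls5) % L + 1 if wraps else hs5 - ls5 + 1
        recs.append((ls5, hs5, length, x, wraps, length > 15000))
    calls = pd.DataFrame(
        recs, columns=["ls5", "hs5", "length", "x_i", "wraps",
                       "possible_insertion"])
    return DeletionCatalog(calls=calls, depth=np.full(L, 100, dtype=np.int64),
                           r_t=r_t, L_r=L_r, min_anchor=min_anchor)
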