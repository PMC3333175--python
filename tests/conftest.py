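import pandas as pd
import pytest

from dupsplice.io_tables import GeneRecord, ParalogPair, RunConfig


def write_tsv(path, rows, columns):
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
    return path


@pytest.fixture
def config():
    return RunConfig()


def make_record(gene_id, n_known, n_all=None, length=300, **kw):
    n_all = n_known if n_all is None else n_all
    return GeneRecord(
        gene_id=gene_id,
        species="testspecies",
        known_peptide_count=n_known,
        all_peptide_count=n_all,
        longest_known_peptide_length=length if n_known else None,
        **kw,
    )


@pytest.fixture
def eight_gene_fixture():
    """Two families + four singletons with hand-assigned AS status.

    Pair (a,b) at identity 95 forms a family at every default criterion;
    pair (c,d) at max identity 50 only below criterion 50 (strict ">").
    Known-peptide counts: a=2, b=3, c=1, d=2, e=2, f=g=h=1.
    """
    counts = {"a": 2, "b": 3, "c": 1, "d": 2, "e": 2, "f": 1, "g": 1, "h": 1}
    records = {g: make_record(g, n) for g, n in counts.items()}
    pairs = [
        ParalogPair.make("a", "b", 95.0, 91.0),
        ParalogPair.make("c", "d", 45.0, 50.0),
    ]
    return records, pairs, counts
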