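import textwrap

import pytest

from fishprobes.gene_models import GeneModel, Isoform


def write_fasta(path, records, width=60):
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


def write_gtf(path, rows):
    """rows: (seqid, feature, start1, end1, strand, gene_id, transcript_id)."""
    with open(path, "w") as fh:
        for seqid, feature, start, end, strand, gid, tid in rows:
            attrs = f'gene_id "{gid}";'
            if tid is not None:
                attrs += f' transcript_id "{tid}";'
            fh.write(f"{seqid}\tt\t{feature}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n")
    return path


def make_gene(gene_id="geneA", strand="+", isoforms=None, reference="chr1", utr5=None):
    isoforms = isoforms or {"t1": [(0, 100)]}
    return GeneModel(
        gene_id=gene_id,
        strand=strand,
        reference_name=reference,
        isoforms=[Isoform(tid, tuple(ex)) for tid, ex in isoforms.items()],
        utr5=list(utr5 or []),
    )


@pytest.fixture
def toy_genome():
    """Dict-backed sequence store (slicing a str mimics an indexed FASTA)."""
    import numpy as np

    rng = np.random.default_rng(7)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=600))
    return {"chr1": seq}
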