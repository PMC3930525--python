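import io

import pytest

from kakspipe.core_formats import NucleotideSequence, write_fasta


@pytest.fixture
def fasta_file(tmp_path):
    """Factory writing NucleotideSequence records to a temp FASTA."""
    def _write(records, name="seqs.fasta"):
        path = tmp_path / name
        write_fasta(records, path)
        return path
    return _write


def make_seq(seq_id: str, bases: str) -> NucleotideSequence:
    return NucleotideSequence(seq_id, bases)
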