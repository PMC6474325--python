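import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from pprfoot.code import default_code_table
from pprfoot.motifs import default_profile
from pprfoot.seqio import SequenceRecord


@pytest.fixture(scope="session")
def profile():
    return default_profile()


@pytest.fixture(scope="session")
def code_table():
    return default_code_table()


@pytest.fixture()
def rna_record():
    def make(residues: str, rec_id: str = "rna") -> SequenceRecord:
        return SequenceRecord(id=rec_id, alphabet="nucleotide", residues=residues)

    return make


@pytest.fixture()
def protein_record():
    def make(residues: str, rec_id: str = "prot") -> SequenceRecord:
        return SequenceRecord(id=rec_id, alphabet="protein", residues=residues)

    return make


PRINTED_CONSENSUS = "(C/U)A(C/U)XXX(U/C)XXXXXGGX(C/U)(U/C)(C/U)(U/C)(U/C)(U/C)"
PROBE_RNA = "UAUAGGCAUUAUUUUUUUUUCU"


@pytest.fixture(scope="session")
def printed_consensus() -> str:
    return PRINTED_CONSENSUS


@pytest.fixture(scope="session")
def probe_rna() -> str:
    return PROBE_RNA


def external_dir() -> Path:
    return Path(__file__).resolve().parents[1] / "data" / "external"
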