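import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tcrep.models import CloneRecord, FrameType, Repertoire, Tissue


def make_repertoire(counts, sample_id="S1", tissue=Tissue.TUMOR, aa_prefix="CASS"):
    """A productive repertoire with one clone per template count."""
    clones = [
        CloneRecord(
            nucleotide_seq=f"TGTGCC{i:06d}",
            amino_acid_seq=f"{aa_prefix}{i:04d}F",
            templates=int(c),
            frame_type=FrameType.IN_FRAME,
        )
        for i, c in enumerate(counts)
    ]
    return Repertoire(sample_id=sample_id, tissue=tissue, clones=clones)


def make_mixed_repertoire(sample_id="S1", tissue=Tissue.TUMOR):
    """3 in-frame + 1 stop + 1 out-of-frame clones."""
    clones = [
        CloneRecord("AAATTTCCC", "CASSAF", 5, FrameType.IN_FRAME),
        CloneRecord("AAATTTCCG", "CASSBF", 3, FrameType.IN_FRAME),
        CloneRecord("AAATTTCCT", "CASSCF", 2, FrameType.IN_FRAME),
        CloneRecord("AAATTTCCA", "", 4, FrameType.HAS_STOP),
        CloneRecord("AAATTTGGG", "", 1, FrameType.OUT_OF_FRAME),
    ]
    return Repertoire(sample_id=sample_id, tissue=tissue, clones=clones)


@pytest.fixture
def mixed_repertoire():
    return make_mixed_repertoire()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240523)


@pytest.fixture(scope="session")
def tiny_cohort():
    from tcrep.simulate import generate_cohort, tiny_config

    return generate_cohort(tiny_config(master_seed=7))


@pytest.fixture(scope="session")
def tiny_cohort_dir(tmp_path_factory, tiny_cohort):
    from tcrep.simulate import write_cohort

    out = tmp_path_factory.mktemp("cohort")
    write_cohort(tiny_cohort, out)
    return out
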