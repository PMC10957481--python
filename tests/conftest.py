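import pandas as pd
import pytest
from hypothesis import settings

from immunodyn.repertoire_io import Clonotype, RepertoireSample

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_sample(counts, patient_id="P1", visit="C0D1"):
    """Build a productive sample from {clone_name: count}."""
    s = RepertoireSample(patient_id=patient_id, visit=visit)
    for i, (name, count) in enumerate(counts.items()):
        s.add(
            Clonotype(
                cdr3_nt=f"TGT{name}",
                cdr3_aa=f"CASS{name}F",
                v_call=f"TRBV{i % 5 + 1}",
                j_call="TRBJ1-1",
                template_count=count,
            )
        )
    return s


@pytest.fixture
def sample_factory():
    return make_sample


@pytest.fixture
def airr_writer(tmp_path):
    """Write rows (nt, aa, v, j, productive, count) to an AIRR TSV."""

    def write(rows, name="sample.tsv", drop_columns=()):
        df = pd.DataFrame(
            [
                {
                    "sequence_id": f"seq{i}",
                    "junction": r[0],
                    "junction_aa": r[1],
                    "v_call": r[2],
                    "j_call": r[3],
                    "productive": r[4],
                    "duplicate_count": r[5],
                }
                for i, r in enumerate(rows)
            ]
        )
        df = df.drop(columns=list(drop_columns))
        path = tmp_path / name
        df.to_csv(path, sep="\t", index=False)
        return path

    return write
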