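import numpy as np
import pandas as pd
import pytest

from propde.io import PeptideTable, ProteinTable, SampleDesign


def make_design(
    n_replicates=4,
    ages=("young", "old"),
    drugs=("EtOH", "Rapa"),
    inductions=("ctrl", "RU"),
    n_batches=2,
    dataset_id="d1",
):
    rows = []
    i = 0
    for age in ages:
        for drug in drugs:
            for ind in inductions:
                for rep in range(1, n_replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"S{i:02d}",
                            "age": age,
                            "drug": drug,
                            "induction": ind,
                            "replicate": rep,
                            "batch": f"b{(rep - 1) % n_batches + 1}",
                            "dataset_id": dataset_id,
                        }
                    )
                    i += 1
    return SampleDesign(pd.DataFrame(rows))


def make_two_group_design(n_per_group=4):
    """Minimal two-condition design (drug varies, everything else constant)."""
    rows = []
    i = 0
    for drug in ("EtOH", "Rapa"):
        for rep in range(1, n_per_group + 1):
            rows.append(
                {
                    "sample_id": f"S{i:02d}",
                    "age": "young",
                    "drug": drug,
                    "induction": "ctrl",
                    "replicate": rep,
                    "batch": "b1",
                    "dataset_id": "d1",
                }
            )
            i += 1
    return SampleDesign(pd.DataFrame(rows))


@pytest.fixture
def design16():
    return make_design()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def protein_table_from_array(x, sample_ids=None, protein_ids=None):
    x = np.asarray(x, dtype=float)
    if sample_ids is None:
        sample_ids = [f"S{i:02d}" for i in range(x.shape[1])]
    if protein_ids is None:
        protein_ids = [f"P{i:04d}" for i in range(x.shape[0])]
    return ProteinTable(
        values=pd.DataFrame(x, index=pd.Index(protein_ids, name="protein_id"), columns=sample_ids)
    )


def peptide_table_from_array(x, proteins=None, scale="log2", sample_ids=None):
    x = np.asarray(x, dtype=float)
    if sample_ids is None:
        sample_ids = [f"S{i:02d}" for i in range(x.shape[1])]
    pep_ids = [f"pep{i}" for i in range(x.shape[0])]
    if proteins is None:
        proteins = [f"prot{i}" for i in range(x.shape[0])]
    values = pd.DataFrame(x, index=pd.Index(pep_ids, name="peptide_id"), columns=sample_ids)
    return PeptideTable(
        values=values,
        proteins=pd.Series(list(proteins), index=values.index, name="protein_id"),
        scale=scale,
    )
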