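import numpy as np
import pytest

from mcspace import ParticleCountMatrix, StudyDesign


@pytest.fixture
def tiny_matrix():
    """Six particles, three OTUs, two subjects, two time points."""
    counts = np.array([
        [5, 3, 0],
        [2, 2, 2],
        [0, 4, 4],
        [7, 0, 1],
        [1, 1, 6],
        [3, 3, 3],
    ])
    return ParticleCountMatrix(
        counts=counts,
        particle_ids=[f"p{i}" for i in range(6)],
        otu_ids=["OTU1", "OTU2", "OTU3"],
        subjects=["A", "A", "A", "B", "B", "B"],
        times=[0.0, 0.0, 1.0, 0.0, 1.0, 1.0],
    )


@pytest.fixture
def csv_trio(tmp_path):
    """Well-formed counts/taxonomy/design CSV files on disk."""
    counts = tmp_path / "counts.csv"
    counts.write_text(
        "particle_id,subject,time,OTU1,OTU2\n"
        "p0,A,0,5,3\n"
        "p1,A,0,2,2\n"
        "p2,A,1,0,4\n"
    )
    taxonomy = tmp_path / "taxonomy.csv"
    taxonomy.write_text(
        "otu,taxonomy\nOTU1,Bacteroides dorei\nOTU2,Agathobacter rectalis\n"
    )
    design = tmp_path / "design.csv"
    design.write_text("time,pert\n0,0\n1,1\n")
    return counts, taxonomy, design


@pytest.fixture
def simple_design():
    return StudyDesign(timepoints=np.array([0.0, 1.0, 2.0, 3.0]),
                       perturbations={"pert": frozenset([1.0, 2.0])})
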