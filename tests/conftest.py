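import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pertconv.meta import DEGTable
from pertconv.semsim import Ontology

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_deg_table(ko_id, genes, log2fc, se, pvalue, n, cell_type="iGLUT_mature"):
    return DEGTable(
        ko_id=ko_id,
        cell_type=cell_type,
        data=pd.DataFrame(
            {
                "gene_id": genes,
                "log2fc": np.asarray(log2fc, dtype=float),
                "se": np.asarray(se, dtype=float),
                "pvalue": np.asarray(pvalue, dtype=float),
                "n": n,
            }
        ),
    )


@pytest.fixture
def toy_ontology():
    """Hand-built DAG with known annotation counts.

    root annotates all four genes; term P annotates {g1, g2} (IC = ln 2);
    term C (child of P) annotates {g1} (IC = ln 4); term Q (child of root)
    annotates {g3, g4} (IC = ln 2).
    """
    parents = {"root": set(), "P": {"root"}, "C": {"P"}, "Q": {"root"}}
    annotations = {
        "g1": {"C"},
        "g2": {"P"},
        "g3": {"Q"},
        "g4": {"Q"},
    }
    for g in annotations:
        annotations[g] = annotations[g] | {"root"}
    return Ontology(parents=parents, annotations=annotations)
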