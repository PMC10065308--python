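import numpy as np
import pandas as pd
import pytest

from cohortoutliers import CohortTable, OutcomeSpec, VariableMetadata


def make_table(columns: dict, metadata: dict | None = None, outcome: str | None = None,
               positive: str = "yes") -> CohortTable:
    """Build a CohortTable from plain dicts.

    ``columns`` maps name -> list of cell values (np.nan for missing);
    ``metadata`` maps name -> (kind, role) or VariableMetadata; defaults
    infer kind from the first non-missing value.
    """
    n = len(next(iter(columns.values())))
    df = pd.DataFrame(columns, index=pd.Index([f"r{i}" for i in range(n)], name="participant_id"))
    meta = {}
    for name in columns:
        if metadata and name in metadata:
            m = metadata[name]
            meta[name] = m if isinstance(m, VariableMetadata) else VariableMetadata(name, *m)
        else:
            col = df[name].dropna()
            kind = "continuous" if col.map(lambda v: isinstance(v, (int, float))).all() else "categorical"
            role = "outcome" if name == outcome else "feature"
            meta[name] = VariableMetadata(name, kind, role=role)
        if meta[name].kind == "continuous":
            df[name] = df[name].astype(float)
        else:
            df[name] = df[name].astype(object).where(df[name].notna(), np.nan)
    spec = OutcomeSpec(outcome, positive) if outcome else None
    return CohortTable(data=df, metadata=meta, outcome=spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20220101)
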