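import numpy as np
import pandas as pd
import pytest

from crossplice.model import PsiTable, SampleDesign, SampleInfo


def make_psi_table(event_values: dict, event_meta: dict | None = None) -> PsiTable:
    """Build a PsiTable from {event_id: {sample: (psi, tier, inc, exc[, b5, b3])}}."""
    events_rows, data_rows = [], []
    samples: list[str] = []
    for event_id, per_sample in event_values.items():
        meta = (event_meta or {}).get(event_id, {})
        events_rows.append(
            {
                "event_id": event_id,
                "gene_id": meta.get("gene_id", f"g_{event_id}"),
                "type": meta.get("type", "AltEx"),
                "coord": meta.get("coord", "chr1:1-2"),
            }
        )
        for sample, vals in per_sample.items():
            if sample not in samples:
                samples.append(sample)
            psi, tier, inc, exc = vals[:4]
            b5, b3 = (vals[4], vals[5]) if len(vals) > 4 else (float("nan"), float("nan"))
            data_rows.append(
                {
                    "event_id": event_id,
                    "sample_id": sample,
                    "psi": psi,
                    "tier": tier,
                    "inc": inc,
                    "exc": exc,
                    "b5": b5,
                    "b3": b3,
                }
            )
    events = pd.DataFrame(events_rows).set_index("event_id")
    return PsiTable(events, pd.DataFrame(data_rows, columns=PsiTable.DATA_COLUMNS), samples)


@pytest.fixture
def two_by_two_design() -> SampleDesign:
    return SampleDesign(
        {
            "c1": SampleInfo("control", "loss", "1", "main"),
            "c2": SampleInfo("control", "loss", "2", "main"),
            "p1": SampleInfo("perturbed", "loss", "1", "main"),
            "p2": SampleInfo("perturbed", "loss", "2", "main"),
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
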