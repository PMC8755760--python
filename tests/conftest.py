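import numpy as np
import pandas as pd
import pytest


@pytest.fixture()
def toy_stop_trials():
    """Hand-checkable stop-signal table: ten go RTs 400..850 in 50 ms steps,
    four stop trials (two responded) with SSDs 200/250/300/350."""
    rows = []
    for i, rt in enumerate(range(400, 900, 50)):
        rows.append(("s1", 1, i, "go", np.nan, float(rt), "press", True))
    stop_spec = [(200.0, 500.0), (250.0, np.nan), (300.0, 520.0), (350.0, np.nan)]
    for j, (ssd, rt) in enumerate(stop_spec):
        responded = np.isfinite(rt)
        rows.append(("s1", 1, 10 + j, "stop", ssd, rt,
                     "press" if responded else "none", not responded))
    return pd.DataFrame(rows, columns=["subject", "run", "trial_index",
                                       "trial_type", "ssd_ms", "rt_ms",
                                       "response", "correct"])
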