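import numpy as np
import pandas as pd

from mbfuse.feature_table import FeatureTable


def make_table(arr, samples=None, features=None):
    arr = np.asarray(arr)
    samples = samples or [f"s{i}" for i in range(arr.shape[0])]
    features = features or [f"f{j}" for j in range(arr.shape[1])]
    return FeatureTable(pd.DataFrame(arr, index=samples, columns=features))
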