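import numpy as np
import pytest

import svscore as s


@pytest.fixture(scope="session")
def panel():
    return s.default_panel()


@pytest.fixture(scope="session")
def rules():
    return s.default_rules()


@pytest.fixture(scope="session")
def small_roi():
    """One modest inflamed ROI shared by read-only tests."""
    return s.generate_roi("inflamed", n_cells=150, size_um=300.0, seed=11)


@pytest.fixture(scope="session")
def scored_small_roi(small_roi, rules):
    roi, mask, truth = small_roi
    table, pgraph, stats, report = s.score_roi(roi, mask, rules)
    return roi, mask, truth, table, pgraph, stats, report


def random_typed_cells(rng, n, size_um=300.0,
                       types=("Tumor", "Stroma", "CD8", "M1", "M2")):
    """A cell table of uniformly random typed centroids (no image behind it)."""
    import pandas as pd
    from svscore.datamodel import CellTable

    panel = s.default_panel()
    xy = rng.uniform(0, size_um, size=(n, 2))
    df = pd.DataFrame({
        "cell_id": np.arange(1, n + 1),
        "centroid_x_px": xy[:, 0],
        "centroid_y_px": xy[:, 1],
        "centroid_x_um": xy[:, 0],
        "centroid_y_um": xy[:, 1],
        "area_px": np.full(n, 1),
    })
    for name in panel.names:
        df[f"mean_{name}"] = 0.0
    table = CellTable(df=df, marker_names=panel.names)
    table.df["cell_type"] = list(rng.choice(types, size=n))
    return table
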