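import numpy as np
import pandas as pd
import pytest

from screensift import (
    GEOMETRY_96,
    ScreenTable,
    SyntheticScreenSpec,
    generate_screen,
)

MINIMAL_HEADER = "Plate number,Well,Well type,Gene symbol,Entrez Gene ID,Signal"


@pytest.fixture
def minimal_csv(tmp_path):
    """Two-record screen file with one data column."""
    path = tmp_path / "screen.csv"
    path.write_text(
        MINIMAL_HEADER + "\n"
        "1,A01,STX16,STX16,8675,0.95\n"
        "1,A02,sample,GENE1,1001,0.10\n"
    )
    return path


def make_table(values_by_plate, well_types=None, column="Signal", geometry=GEOMETRY_96,
               control_types=("STX16", "GFP"), reagents=None, genes=None):
    """Build a small in-memory ScreenTable from per-plate value lists."""
    rows = []
    gene_ids: dict[str, int] = {}
    k = 0
    for plate, values in values_by_plate.items():
        for idx, v in enumerate(values):
            i, j = divmod(idx, geometry.n_cols)
            symbol = genes[k] if genes else f"G{k + 1}"
            entrez = gene_ids.setdefault(symbol, 9_100_001 + len(gene_ids))
            rows.append(
                {
                    "plate": plate,
                    "well": geometry.format_well(i, j),
                    "well_type": well_types[k] if well_types else "sample",
                    "gene_symbol": symbol,
                    "entrez_id": entrez,
                    "reagent_id": reagents[k] if reagents else None,
                    column: v,
                }
            )
            k += 1
    df = pd.DataFrame(rows)
    df["entrez_id"] = df["entrez_id"].astype("Int64")
    return ScreenTable(
        records=df,
        data_columns=[column],
        geometry=geometry,
        control_types=control_types,
    )


@pytest.fixture
def small_screen():
    """A compact seeded synthetic screen (2 plates, 96-well, replicates)."""
    spec = SyntheticScreenSpec(n_plates=2, geometry=GEOMETRY_96, n_hits=5)
    return generate_screen(spec, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
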