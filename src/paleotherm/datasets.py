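"""Bundled example dataset: published HMC values, composite supertree,
stratigraphic ranges and extant states.

See ``paleotherm/data/README.md`` for provenance. The tree and the extant
species list are reconstructions of non-redistributable supplementary
material, so ensemble results computed from them are approximate.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import dendropy
import pandas as pd

from .histology import SpecimenRecord
from .logistic import LogisticModel, classify, predict_pend
from .tree_time import StratRange, read_newick, read_ranges

__all__ = [
    "data_path",
    "load_hmc_table",
    "load_supertree",
    "load_ranges",
    "load_extant_states",
    "specimen_records_from_hmc",
]


def data_path(name: str) -> Path:
    """Filesystem path of a bundled data file."""
    path = Path(str(resources.files("paleotherm") / "data" / name))
    if not path.exists():
        raise FileNotFoundError(f"no bundled data file {name!r}")
    return path


def load_hmc_table() -> pd.DataFrame:
    """Published per-specimen HMC values with printed p_end and status."""
    # keep the printed probability as text so its significant figures
    # (including trailing zeros) are preserved for regression tests
    return pd.read_csv(data_path("table1_hmc.tsv"), sep="\t",
                       dtype={"pend_printed": str})


def load_supertree() -> dendropy.Tree:
    """Composite fossil+extant cladogram with labeled internal nodes."""
    return read_newick(data_path("supertree.nwk"))


def load_ranges() -> list[StratRange]:
    return read_ranges(data_path("strat_ranges.tsv"))


def load_extant_states() -> dict[str, int]:
    from .ensemble import read_states_table

    return read_states_table(data_path("extant_states.tsv"))


def specimen_records_from_hmc(
    table: pd.DataFrame | None = None,
    model: LogisticModel = LogisticModel(),
) -> list[SpecimenRecord]:
    """Classify a per-specimen HMC table (columns specimen_id, taxon, hmc_um).

    This is the entry point when canal-level measurements are unavailable
    and only published harmonic means are (as in the bundled dataset).
    """
    df = table if table is not None else load_hmc_table()
    records = []
    for row in df.itertuples():
        p = predict_pend(float(row.hmc_um), model)
        records.append(
            SpecimenRecord(
                specimen_id=str(row.specimen_id),
                taxon=str(row.taxon),
                hmc=float(row.hmc_um),
                p_end=p,
                status=classify(p, model),
            )
        )
    return records
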