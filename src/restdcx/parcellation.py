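"""Grey-matter parcellation with resting-state-network attribution.

The bundled table covers 82 grey-matter parcels: the 68 cortical regions of
the Desikan-Killiany atlas plus 14 subcortical structures (brainstem and
cerebellum excluded). Each parcel carries exactly one of the seven canonical
resting-state-network (RSN) labels of the Yeo parcellation. Because only few
medial-temporal regions map onto the limbic system, the limbic network is the
smallest subnetwork — a property downstream statistics must tolerate.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .exceptions import SchemaError

#: Canonical RSN label order; index+1 is the numeric network id used by the
#: synthetic-cohort generator.
RSN_LABELS = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default_mode",
)

N_PARCELS = 82

_COLUMNS = ["parcel_id", "name", "hemisphere", "rsn_label"]


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    if list(table.columns) != _COLUMNS:
        raise SchemaError(f"parcellation columns must be {_COLUMNS}, got {list(table.columns)}")
    if len(table) != N_PARCELS:
        raise SchemaError(f"parcellation must have {N_PARCELS} rows, got {len(table)}")
    if table["parcel_id"].duplicated().any():
        raise SchemaError("duplicated parcel_id in parcellation table")
    unknown = set(table["rsn_label"]) - set(RSN_LABELS)
    if unknown:
        raise SchemaError(f"unknown rsn_label values: {sorted(unknown)}")
    if set(table["hemisphere"]) != {"L", "R"}:
        raise SchemaError("both hemispheres must be represented")
    return table.reset_index(drop=True)


def load_parcellation(path=None) -> pd.DataFrame:
    """Load and validate a parcellation table.

    Parameters
    ----------
    path
        TSV with columns ``parcel_id, name, hemisphere, rsn_label``.
        ``None`` loads the bundled 82-parcel fixture.
    """
    if path is None:
        src = resources.files("restdcx.data").joinpath("parcellation_82.tsv")
        with resources.as_file(src) as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    return _validate(table)


def rsn_members(table: pd.DataFrame) -> dict[str, list[int]]:
    """Zero-based node indices of each RSN, in canonical label order."""
    return {
        rsn: list(table.index[table["rsn_label"] == rsn])
        for rsn in RSN_LABELS
    }


def numeric_rsn_labels(table: pd.DataFrame) -> list[int]:
    """Per-parcel network id in 1..7 following :data:`RSN_LABELS` order."""
    lookup = {name: i + 1 for i, name in enumerate(RSN_LABELS)}
    return [lookup[v] for v in table["rsn_label"]]
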