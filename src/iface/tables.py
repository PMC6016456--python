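"""Tabular input/output: every table the pipeline reads or writes is TSV
with a header row (fit reports are JSON). Thin wrappers over pandas."""

from __future__ import annotations

import json
import os
from typing import Mapping, Sequence

import pandas as pd

from .contacts import AveragedProfile, ContactSet, DomainPartition, PrevalenceProfile
from .errors import InputError
from .structio import ResidueKey

__all__ = [
    "contacts_frame",
    "profile_frame",
    "averaged_frame",
    "read_chain_roles",
    "read_domain_partition",
    "read_score_table",
    "read_titration_table",
    "write_json_report",
]


def contacts_frame(cs: ContactSet) -> pd.DataFrame:
    rows = [
        {
            "receptor_chain": r[0], "receptor_resnum": r[1], "receptor_icode": r[2],
            "ligand_chain": l[0], "ligand_resnum": l[1], "ligand_icode": l[2],
        }
        for r, l in sorted(cs.pairs)
    ]
    return pd.DataFrame(rows, columns=[
        "receptor_chain", "receptor_resnum", "receptor_icode",
        "ligand_chain", "ligand_resnum", "ligand_icode",
    ])


def profile_frame(profile: PrevalenceProfile) -> pd.DataFrame:
    rows = [
        {"chain": k[0], "resnum": k[1], "icode": k[2], "frequency": f}
        for k, f in sorted(profile.frequencies.items())
    ]
    return pd.DataFrame(rows, columns=["chain", "resnum", "icode", "frequency"])


def averaged_frame(
    averaged: AveragedProfile, partition: DomainPartition | None = None
) -> pd.DataFrame:
    rows = []
    for key in sorted(averaged.mean):
        row = {
            "chain": key[0], "resnum": key[1], "icode": key[2],
            "mean": averaged.mean[key], "sd": averaged.sd[key],
        }
        if partition is not None:
            row["domain"] = partition.assign(key)
        rows.append(row)
    return pd.DataFrame(rows)


def read_chain_roles(path: str | os.PathLike) -> tuple[set[str], set[str]]:
    """Plain-text chain-role file: lines of ``<chain>\t<receptor|ligand>``."""
    receptor: set[str] = set()
    ligand: set[str] = set()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2 or parts[1] not in ("receptor", "ligand"):
                raise InputError(f"{path}: line {lineno}: expected '<chain> receptor|ligand'")
            (receptor if parts[1] == "receptor" else ligand).add(parts[0])
    if not receptor or not ligand:
        raise InputError(f"{path}: need at least one receptor and one ligand chain")
    return receptor, ligand


def read_domain_partition(path: str | os.PathLike) -> DomainPartition:
    """Domain partition TSV with columns domain, chain, start, end."""
    df = pd.read_csv(path, sep="\t")
    required = {"domain", "chain", "start", "end"}
    if not required <= set(df.columns):
        raise InputError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    intervals: dict[str, list[tuple[str, int, int]]] = {}
    for _, row in df.iterrows():
        intervals.setdefault(str(row["domain"]), []).append(
            (str(row["chain"]), int(row["start"]), int(row["end"]))
        )
    return DomainPartition(intervals=intervals)


def read_score_table(path: str | os.PathLike) -> pd.DataFrame:
    """Docking score table: TSV with columns pose_id, score."""
    df = pd.read_csv(path, sep="\t")
    if not {"pose_id", "score"} <= set(df.columns):
        raise InputError(f"{path}: expected columns pose_id, score")
    return df


def read_titration_table(path: str | os.PathLike) -> pd.DataFrame:
    """Two-column concentration/signal table (TSV or CSV, sniffed from header)."""
    with open(path) as handle:
        header = handle.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise InputError(f"{path}: expected two columns (concentration, signal)")
    return df


def write_json_report(path: str | os.PathLike, payload: Mapping) -> None:
    def default(obj):
        import numpy as np

        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True, default=default)
        handle.write("\n")
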