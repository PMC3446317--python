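"""Readers and writers for the flat-file formats the toolkit exchanges.

All coordinates are 0-based, half-open; the pattern writer documents this in
its header.  Strain-distribution patterns follow the published dialect: a
TEV in the reference lineage (side ``B6plus``) is encoded ``1`` where a
strain matches the reference and ``DEL`` where the element is absent; a
non-reference insertion (``B6minus``) is ``0`` where a strain matches the
reference and ``INS`` where the element is present.  ``NA`` marks an
uncalled genotype on either side.
"""

from __future__ import annotations

import pandas as pd

TEV_COLUMNS = [
    "tev_id", "side", "chrom", "start", "end", "te_class", "family",
    "structure", "strand", "size_class",
]

ANCHOR_COLUMNS = [
    "strain", "chrom", "pos", "anchor_orientation", "mapq",
    "mate_family", "mate_mapped",
]


def write_tev_bed(records: pd.DataFrame, path) -> None:
    """Write TEV records as BED6+ (name = class:family:structure)."""
    df = records.copy()
    name = (
        df["tev_id"].astype(str) + "|"
        + df["te_class"].astype(str) + ":"
        + df["family"].astype(str) + ":"
        + df["structure"].astype(str)
    )
    bed = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start"].astype(int),
        "end": df["end"].astype(int),
        "name": name,
        "score": 0,
        "strand": df["strand"].fillna("."),
    })
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_tev_bed(path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    ids, classes, fams, structs = [], [], [], []
    for nm in bed["name"]:
        tev_id, rest = nm.split("|", 1)
        cls, fam, struct = rest.split(":")
        ids.append(tev_id)
        classes.append(cls)
        fams.append(fam)
        structs.append(struct)
    return pd.DataFrame({
        "tev_id": ids,
        "chrom": bed["chrom"],
        "start": bed["start"].astype(int),
        "end": bed["end"].astype(int),
        "te_class": classes,
        "family": fams,
        "structure": structs,
        "strand": bed["strand"],
    })


def write_pattern(records: pd.DataFrame, presence: pd.DataFrame, path) -> None:
    """Write the strain-distribution-pattern TSV.

    ``records`` carries one row per TEV (columns including ``tev_id`` and
    ``side``); ``presence`` is the tev x strain matrix of {0,1,NA}.
    """
    strains = list(presence.columns)
    rec = records.set_index("tev_id")
    with open(path, "w") as fh:
        fh.write("# coordinates are 0-based, half-open\n")
        cols = ["tev_id", "side", "chrom", "start", "end",
                "te_class", "family", "structure"] + strains
        fh.write("\t".join(cols) + "\n")
        for tev_id, row in presence.iterrows():
            r = rec.loc[tev_id]
            side = r["side"]
            cells = []
            for s in strains:
                v = row[s]
                if pd.isna(v):
                    cells.append("NA")
                elif side == "B6plus":
                    cells.append("1" if int(v) == 1 else "DEL")
                else:
                    cells.append("INS" if int(v) == 1 else "0")
            fh.write("\t".join(
                [str(tev_id), side, str(r["chrom"]), str(int(r["start"])),
                 str(int(r["end"])), str(r["te_class"]), str(r["family"]),
                 str(r["structure"])] + cells) + "\n")


def read_pattern(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a pattern TSV; returns (records, presence {0,1,NA})."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    meta_cols = ["tev_id", "side", "chrom", "start", "end",
                 "te_class", "family", "structure"]
    strains = [c for c in df.columns if c not in meta_cols]
    records = df[meta_cols].copy()
    records["start"] = records["start"].astype(int)
    records["end"] = records["end"].astype(int)

    def decode(side, v):
        if v == "NA":
            return float("nan")
        if side == "B6plus":
            return 1 if v == "1" else 0
        return 1 if v == "INS" else 0

    presence = pd.DataFrame(
        [[decode(side, v) for v in row]
         for side, row in zip(df["side"], df[strains].to_numpy())],
        index=df["tev_id"], columns=strains,
    )
    presence.index.name = "tev_id"
    return records, presence


def write_anchors(anchors: pd.DataFrame, path) -> None:
    out = anchors[ANCHOR_COLUMNS].copy()
    out["mate_family"] = out["mate_family"].fillna("")
    out.to_csv(path, sep="\t", index=False)


def read_anchors(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"mate_family": str})
    df["mate_family"] = df["mate_family"].replace("", pd.NA)
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    """Gene x sample count matrix; sample headers are strain.replicate."""
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")
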