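"""Feature annotation table: identities, biotypes, lengths, gene-exon structure.

The table is a thin wrapper around a :class:`pandas.DataFrame` indexed by
feature id with columns ``biotype``, ``chrom``, ``start``, ``end``,
``length_bp`` and ``parent_gene_id`` (NA for top-level features). All
coordinates are GFF3-style 1-based inclusive; a gene's length is the length
of the union of its exon intervals, which is what the RPKM denominator uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DataError, ParseError

COLUMNS = ["biotype", "chrom", "start", "end", "length_bp", "parent_gene_id"]


def union_length(intervals: Iterable[Tuple[int, int]]) -> int:
    """Total length of the union of 1-based inclusive intervals.

    Overlapping or bookended intervals are merged before summing, so e.g.
    [1, 100] and [51, 150] contribute 150 bases, not 200.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    if not ivs:
        return 0
    total = 0
    cur_s, cur_e = ivs[0]
    for s, e in ivs[1:]:
        if s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    total += cur_e - cur_s + 1
    return total


@dataclass
class FeatureTable:
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(COLUMNS) - set(self.df.columns)
        if missing:
            raise DataError(f"FeatureTable missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def top_level(self) -> pd.DataFrame:
        """Features without a parent: genes and standalone ncRNAs."""
        return self.df[self.df["parent_gene_id"].isna()]

    @property
    def exons(self) -> pd.DataFrame:
        return self.df[self.df["parent_gene_id"].notna()]

    def lengths(self) -> pd.Series:
        return self.df["length_bp"]

    def validate(self) -> None:
        if not self.df.index.is_unique:
            dup = self.df.index[self.df.index.duplicated()][0]
            raise DataError(f"duplicate feature_id: {dup!r}")
        exons = self.exons
        if len(exons):
            parents = set(exons["parent_gene_id"])
            known = set(self.top_level.index)
            orphans = parents - known
            if orphans:
                raise DataError(f"exon Parent not found among genes: {sorted(orphans)[:5]}")
            not_gene = {
                p for p in parents if self.df.loc[p, "biotype"] != "gene"
            }
            if not_gene:
                raise DataError(f"exon Parent is not a gene: {sorted(not_gene)[:5]}")
            # gene length must equal the union of its exon intervals
            for gid, sub in exons.groupby("parent_gene_id"):
                expect = union_length(zip(sub["start"], sub["end"]))
                got = int(self.df.loc[gid, "length_bp"])
                if got != expect:
                    raise DataError(
                        f"gene {gid!r}: length_bp {got} != exon union length {expect}"
                    )
        if (self.df["length_bp"] <= 0).any():
            bad = self.df.index[self.df["length_bp"] <= 0][0]
            raise DataError(f"feature {bad!r}: nonpositive length_bp")

    # ------------------------------------------------------------------ I/O

    def to_gff3(self, path: str | Path) -> None:
        """Write as GFF3: top-level features typed by biotype, exons with Parent."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for fid, row in self.df.iterrows():
                if pd.isna(row["parent_gene_id"]):
                    ftype = row["biotype"]
                    attrs = f"ID={fid}"
                else:
                    ftype = "exon"
                    attrs = f"ID={fid};Parent={row['parent_gene_id']}"
                fh.write(
                    f"{row['chrom']}\texopattern\t{ftype}\t{int(row['start'])}\t"
                    f"{int(row['end'])}\t.\t+\t.\t{attrs}\n"
                )

    @staticmethod
    def from_gff3(path: str | Path) -> "FeatureTable":
        """Read a GFF3 annotation into a FeatureTable.

        Gene lengths are recomputed as the union of each gene's exon
        intervals; features without exon children use their own interval.
        Raises :class:`ParseError` with a line number on malformed lines and
        :class:`DataError` when an exon references an unknown Parent.
        """
        import gffutils

        path = Path(path)
        _prescan_gff3(path)
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="error", keep_order=True
        )
        rows = []
        exon_ivs: dict[str, list[Tuple[int, int]]] = {}
        for feat in db.all_features():
            parent = feat.attributes.get("Parent", [None])[0]
            fid = feat.id
            if feat.featuretype == "exon" or parent is not None:
                if parent is None:
                    raise DataError(f"exon {fid!r} has no Parent attribute")
                exon_ivs.setdefault(parent, []).append((feat.start, feat.end))
                biotype = "exon"
            else:
                biotype = feat.featuretype
            rows.append(
                {
                    "feature_id": fid,
                    "biotype": biotype,
                    "chrom": feat.seqid,
                    "start": feat.start,
                    "end": feat.end,
                    "length_bp": feat.end - feat.start + 1,
                    "parent_gene_id": parent,
                }
            )
        df = pd.DataFrame(rows).set_index("feature_id")
        df["parent_gene_id"] = df["parent_gene_id"].astype(object)
        for gid, ivs in exon_ivs.items():
            if gid not in df.index:
                raise DataError(f"exon Parent {gid!r} not present in file")
            df.loc[gid, "length_bp"] = union_length(ivs)
        table = FeatureTable(df)
        table.validate()
        return table


def _prescan_gff3(path: Path) -> None:
    """Cheap syntax check so parse errors carry a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields, "
                                 f"got {len(fields)}")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start < 1 or end < start:
                raise ParseError(f"{path}:{lineno}: bad interval {start}..{end}")


def make_feature_table(
    records: Sequence[dict],
) -> FeatureTable:
    """Build and validate a FeatureTable from plain records (test/construction aid)."""
    df = pd.DataFrame(records).set_index("feature_id")
    for col in COLUMNS:
        if col not in df.columns:
            df[col] = np.nan if col == "parent_gene_id" else 0
    table = FeatureTable(df[COLUMNS])
    table.validate()
    return table
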