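"""Readers and writers for pedigree, genotype, phenotype and matrix files.

All tables are delimiter-sniffed CSV/TSV with a header row.  Unknown
parents are coded "0" (an empty field is also accepted).  Ids are
opaque strings mapped internally to dense indices in pedigree order.
Every reader rejects malformed input with an error naming the offending
record; nothing is silently coerced.
"""

from __future__ import annotations

import csv
import logging

import numpy as np
import pandas as pd

from .genotype import AlleleFrequencies, GenotypeMatrix
from .matrices import RelationshipMatrix
from .pedigree import Pedigree

log = logging.getLogger(__name__)

MISSING_PARENT = {"0", "", "na", "nan", ".", "none"}
_PLINK_META = {"FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"}


def _read_table(path) -> pd.DataFrame:
    """Delimiter-sniffed CSV/TSV with a header row."""
    with open(path, "r", newline="") as fh:
        sample = fh.read(8192)
    try:
        dialect = csv.Sniffer().sniff(sample, delimiters=",\t; ")
        sep = dialect.delimiter
    except csv.Error:
        sep = ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def read_pedigree(path) -> Pedigree:
    """Read an animal/sire/dam table; returns a parent-first pedigree.

    Rows may appear in any order; the pedigree is topologically
    reordered.  Duplicate animals and cycles are hard errors naming an
    offending animal.
    """
    df = _read_table(path)
    need = {"animal", "sire", "dam"}
    if not need.issubset(df.columns):
        raise ValueError(
            f"pedigree file must have columns animal, sire, dam; "
            f"found {list(df.columns)}"
        )
    recs = []
    for row in df.itertuples(index=False):
        a = str(getattr(row, "animal")).strip()
        if a == "" or a.lower() in MISSING_PARENT:
            raise ValueError(f"invalid animal id {a!r} in pedigree")
        s = str(getattr(row, "sire")).strip()
        d = str(getattr(row, "dam")).strip()
        recs.append(
            (
                a,
                None if s.lower() in MISSING_PARENT else s,
                None if d.lower() in MISSING_PARENT else d,
            )
        )
    ped = Pedigree.from_records(recs)
    log.info("read pedigree: %d animals, %d founders", ped.n, len(ped.founders))
    return ped


def write_pedigree(ped: Pedigree, path) -> None:
    rows = []
    for k, a in enumerate(ped.ids):
        s = ped.ids[ped.sire[k]] if ped.sire[k] >= 0 else "0"
        d = ped.ids[ped.dam[k]] if ped.dam[k] >= 0 else "0"
        rows.append((a, s, d))
    pd.DataFrame(rows, columns=["animal", "sire", "dam"]).to_csv(
        path, index=False
    )


def read_genotypes(path) -> GenotypeMatrix:
    """Read a dosage table (rows = individuals, columns = markers).

    The first column (``id``, or PLINK .raw's ``IID``) labels the
    individual; PLINK metadata columns (FID/PAT/MAT/SEX/PHENOTYPE) are
    ignored.  Entries must be 0, 1, 2 or missing (empty / NA); anything
    else is a hard error naming the cell.
    """
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ("," if "," in header else None)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                     engine="python" if sep is None else "c")
    raw_cols = list(df.columns)
    upper = [c.upper() for c in raw_cols]
    if "IID" in upper:
        id_col = raw_cols[upper.index("IID")]
        marker_cols = [
            c for c, u in zip(raw_cols, upper) if u not in _PLINK_META
        ]
    else:
        id_col = raw_cols[0]
        marker_cols = raw_cols[1:]
    ids = df[id_col].astype(str).str.strip().tolist()
    dup = pd.Series(ids).duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate individual id {ids[int(dup.idxmax())]!r} in genotypes"
        )
    vals = np.full((len(ids), len(marker_cols)), np.nan)
    for j, c in enumerate(marker_cols):
        col = df[c].str.strip().str.lower()
        missing = col.isin(("", "na", "nan", "."))
        ok = col.isin(("0", "1", "2"))
        bad = ~(missing | ok)
        if bad.any():
            i = int(bad.idxmax())
            raise ValueError(
                f"invalid dosage {df[c].iloc[i]!r} for individual "
                f"{ids[i]!r}, marker {c!r}"
            )
        vals[ok.to_numpy(), j] = col[ok].astype(float)
    gm = GenotypeMatrix(ids, [str(c) for c in marker_cols], vals)
    log.info("read genotypes: %d individuals x %d markers", gm.n, gm.m)
    return gm


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(gm.dosages, columns=gm.markers)
    # integral dosages print as integers; imputed fractional values as-is
    with np.errstate(invalid="ignore"):
        if np.all(np.isnan(gm.dosages) | (gm.dosages == np.round(gm.dosages))):
            df = df.astype("Int64")
    df.insert(0, "id", gm.ids)
    df.to_csv(path, index=False)


PHENO_COLUMNS = [
    "cow_id", "tne", "nge", "year", "month", "program", "technician",
    "age_months",
]


def read_phenotypes(path, count_traits: bool = True) -> pd.DataFrame:
    """Read the flush-record table (one row per superovulation treatment).

    With ``count_traits`` (the default, matching real embryo-count
    records) trait values must be non-negative integers and NGE <= TNE
    must hold in every row -- NGE counts good embryos among the TNE
    collected, so a violation indicates corrupted data.  Synthetic data
    on the model's raw Gaussian scale is read with
    ``count_traits=False``, which skips those two checks.
    """
    df = _read_table(path)
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file lacks columns: {missing}")
    out = df[PHENO_COLUMNS].copy()
    for c in ("tne", "nge", "age_months"):
        try:
            out[c] = out[c].astype(float)
        except ValueError as err:
            raise ValueError(f"non-numeric value in column {c!r}: {err}") from None
    for c in ("year", "month", "program", "technician"):
        blank = out[c].astype(str).str.strip() == ""
        if blank.any():
            raise ValueError(
                f"missing {c!r} level in phenotype row {int(blank.idxmax())}"
            )
    if count_traits:
        for c in ("tne", "nge"):
            v = out[c]
            bad = (v < 0) | (v != np.round(v))
            if bad.any():
                i = int(bad.idxmax())
                raise ValueError(
                    f"{c} must be a non-negative integer; row {i} has "
                    f"{v.iloc[i]!r}"
                )
        viol = out["nge"] > out["tne"]
        if viol.any():
            i = int(viol.idxmax())
            raise ValueError(
                f"row {i}: NGE ({out['nge'].iloc[i]}) exceeds TNE "
                f"({out['tne'].iloc[i]}); NGE counts a subset of the "
                "collected embryos"
            )
    out["cow_id"] = out["cow_id"].astype(str)
    log.info(
        "read phenotypes: %d records, %d cows",
        len(out),
        out["cow_id"].nunique(),
    )
    return out


def write_phenotypes(ph: pd.DataFrame, path) -> None:
    ph.to_csv(path, index=False, float_format="%.10g")


def write_matrix(M: RelationshipMatrix, path) -> None:
    """Labeled dense CSV at full stored precision (round-trip exact)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["kind", M.kind])
        w.writerow(["id"] + M.ids)
        for i, a in enumerate(M.ids):
            w.writerow([a] + [repr(float(v)) for v in M.values[i]])


def read_matrix(path, expect_ids=None) -> RelationshipMatrix:
    with open(path, "r", newline="") as fh:
        r = csv.reader(fh)
        first = next(r)
        if first[0] != "kind":
            raise ValueError("matrix file lacks a 'kind' header line")
        kind = first[1]
        hdr = next(r)
        ids = hdr[1:]
        vals = np.empty((len(ids), len(ids)))
        for i, row in enumerate(r):
            if row[0] != ids[i]:
                raise ValueError(
                    f"matrix row label {row[0]!r} does not match header "
                    f"{ids[i]!r}"
                )
            vals[i] = [float(v) for v in row[1:]]
    if expect_ids is not None and list(map(str, expect_ids)) != ids:
        raise ValueError("matrix ids do not match the expected id list")
    return RelationshipMatrix(ids, vals, kind)


def write_frequencies(freqs: AlleleFrequencies, path) -> None:
    pd.DataFrame({"marker": freqs.markers, "p": freqs.p}).to_csv(
        path, index=False, float_format="%.10g"
    )
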