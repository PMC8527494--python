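"""Readers and writers for the text formats the pipeline touches.

PLINK text (PED/MAP) with allele-pair encoding ('0 0' = missing), a plain
dosage TSV, and the phenotype TSV (id, herd, sex, trait columns). Readers
preserve file order; the counted allele of a marker is the first non-missing
allele encountered in the PED unless an override is supplied, a convention
that leaves all downstream quantities unchanged (the GRM is fold-invariant
and dosage coding is symmetric under allele swap).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from merinogp.containers import GenotypeMatrix

VALID_ALLELES = {"A", "C", "G", "T", "0"}


def read_plink_text(
    ped_path: str | Path,
    map_path: str | Path,
    counted_alleles: dict[str, str] | None = None,
) -> GenotypeMatrix:
    """Read PED/MAP files into a dosage matrix.

    Dosage is the count of the counted allele per marker; '0 0' allele
    pairs become NaN. ``counted_alleles`` optionally maps marker id to the
    allele to count, overriding the first-seen convention.
    """
    markers = _read_map(map_path)
    m = len(markers)

    ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise ValueError(
                    f"PED line {lineno}: expected {6 + 2 * m} fields for {m} markers, "
                    f"got {len(fields)}"
                )
            ids.append(fields[1])
            alleles = fields[6:]
            bad = set(alleles) - VALID_ALLELES
            if bad:
                raise ValueError(f"PED line {lineno}: invalid allele symbols {sorted(bad)}")
            allele_rows.append(alleles)

    n = len(ids)
    a_mat = np.array(allele_rows, dtype="U1").reshape(n, m, 2) if n else np.empty((0, m, 2), "U1")

    counted = np.empty(m, dtype="U1")
    other = np.empty(m, dtype="U1")
    dosages = np.full((n, m), np.nan)
    for j in range(m):
        col = a_mat[:, j, :]
        observed = col[col != "0"]
        mid = str(markers.at[j, "id"])
        if counted_alleles and mid in counted_alleles:
            c = counted_alleles[mid]
        elif observed.size:
            c = observed[0]
        else:
            c = "0"
        counted[j] = c
        alts = [a for a in np.unique(observed) if a != c]
        if len(alts) > 1:
            raise ValueError(f"marker {mid} has more than two alleles: {c}, {alts}")
        other[j] = alts[0] if alts else "0"
        non_missing = (col != "0").all(axis=1)
        dosages[non_missing, j] = (col[non_missing] == c).sum(axis=1)

    markers["a1"] = counted
    markers["a2"] = other
    return GenotypeMatrix(dosages, ids, markers)


def _read_map(map_path: str | Path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise ValueError(f"MAP line {lineno}: expected 4 fields, got {len(fields)}")
            chrom, mid, _cm, pos = fields
            rows.append((mid, chrom, int(pos)))
    df = pd.DataFrame(rows, columns=["id", "chrom", "pos"])
    if df["id"].duplicated().any():
        raise ValueError("duplicate marker ids in MAP file")
    return df


def write_plink_text(gm: GenotypeMatrix, ped_path: str | Path, map_path: str | Path) -> None:
    """Write PED/MAP; inverse of :func:`read_plink_text` on integer dosages.

    Missing dosages become '0 0'. Fractional (imputed) dosages cannot be
    expressed as allele pairs and raise.
    """
    d = gm.dosages
    finite = np.isfinite(d)
    if not np.array_equal(d[finite], np.rint(d[finite])):
        raise ValueError("PED output requires integer dosages; write a TSV for imputed data")

    with open(map_path, "w") as fh:
        for _, mk in gm.markers.iterrows():
            fh.write(f"{mk['chrom']}\t{mk['id']}\t0\t{int(mk['pos'])}\n")

    a1 = gm.markers["a1"].to_numpy(dtype="U1")
    a2 = gm.markers["a2"].to_numpy(dtype="U1")
    pair_for = {
        2: lambda j: f"{a1[j]} {a1[j]}",
        1: lambda j: f"{a1[j]} {a2[j]}",
        0: lambda j: f"{a2[j]} {a2[j]}",
    }
    with open(ped_path, "w") as fh:
        for i, iid in enumerate(gm.individual_ids):
            pairs = [
                "0 0" if not finite[i, j] else pair_for[int(d[i, j])](j)
                for j in range(gm.n_markers)
            ]
            fh.write(f"FAM {iid} 0 0 0 -9 " + " ".join(pairs) + "\n")


def read_matrix_tsv(path: str | Path, allow_fractional: bool = False) -> GenotypeMatrix:
    """Read a dosage TSV: header of marker ids, first column individual id.

    Cells must be 0, 1, 2 or NA (empty also accepted as missing);
    ``allow_fractional`` admits any value in [0, 2], for matrices filled
    with expected dosages by the imputer.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    iid_col = df.columns[0]
    ids = df[iid_col].tolist()
    marker_ids = list(df.columns[1:])
    vals = df[marker_ids].to_numpy(dtype=object)
    dosages = np.full(vals.shape, np.nan)
    for (i, j), cell in np.ndenumerate(vals):
        cell = cell.strip()
        if cell in ("NA", "", "nan"):
            continue
        if allow_fractional:
            try:
                x = float(cell)
            except ValueError:
                x = np.nan
            ok = np.isfinite(x) and 0.0 <= x <= 2.0
        else:
            ok = cell in ("0", "1", "2")
            x = float(cell) if ok else np.nan
        if not ok:
            raise ValueError(f"invalid dosage {cell!r} at row {i + 1}, marker {marker_ids[j]}")
        dosages[i, j] = x
    markers = pd.DataFrame(
        {"id": marker_ids, "chrom": "1", "pos": np.arange(1, len(marker_ids) + 1),
         "a1": "A", "a2": "G"}
    )
    return GenotypeMatrix(dosages, ids, markers)


def write_matrix_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(gm.marker_ids) + "\n")
        for i, iid in enumerate(gm.individual_ids):
            cells = [
                "NA" if not np.isfinite(v) else (str(int(v)) if v == int(v) else repr(v))
                for v in gm.dosages[i]
            ]
            fh.write(iid + "\t" + "\t".join(cells) + "\n")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a phenotype TSV with columns id, herd, sex, trait1..traitK.

    Trait columns are parsed as floats with blank/NA as missing; herd and
    sex become pandas categoricals. Duplicate ids raise.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    required = {"id", "herd", "sex"}
    if not required.issubset(df.columns):
        raise ValueError(f"phenotype file must have columns {sorted(required)}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate individual id {dup!r} in phenotype file")
    df["herd"] = df["herd"].astype(str).astype("category")
    df["sex"] = df["sex"].astype(str).astype("category")
    for col in df.columns.difference(["id", "herd", "sex"]):
        df[col] = pd.to_numeric(df[col], errors="raise")
    return df


def write_phenotypes(phenos: pd.DataFrame, path: str | Path) -> None:
    phenos.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_marker_list(path: str | Path) -> list[str]:
    """One marker id per line."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_marker_list(ids: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for mid in ids:
            fh.write(str(mid) + "\n")
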