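"""Plain-text file formats for crosses, outlines and candidate loci.

Cross files are CSV with a three-line header block followed by one row
per individual::

    id,sex,score,...,M01,M02,...
    ,,,,X,X,...          <- chromosome per marker
    ,,,,0.0,4.4,...      <- cM position per marker
    F2_0001,M,0.31,...,A,H,B,-,...

Genotype codes are A (homozygous/hemizygous b3852-like), H
(heterozygous), B (homozygous/hemizygous Sam-like) and ``-`` for
missing.  Reading and writing round-trip losslessly; individuals with
every genotype missing load with their genotyped flag off (the
selective-genotyping convention).

Outline files are long-format tables: outline_id, point_index, x, y and
an optional side column, one row per vertex, header required.
"""

from __future__ import annotations

import csv

import numpy as np
import pandas as pd

from .core import MISSING, GeneticMap, Population
from .enrichment import CandidateSet
from .morphometrics import RawOutline

__all__ = [
    "write_cross",
    "read_cross",
    "write_outlines",
    "read_outlines",
    "read_candidates",
    "write_candidates",
]

_CODE_TO_CHAR = {0: "A", 1: "H", 2: "B", MISSING: "-"}
_CHAR_TO_CODE = {"A": 0, "H": 1, "B": 2, "-": MISSING, "−": MISSING}


def write_cross(pop, path):
    """Write a population to a cross CSV file."""
    pheno_cols = list(pop.phenotypes.columns)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "sex"] + pheno_cols + list(pop.gmap.names))
        w.writerow(["", ""] + [""] * len(pheno_cols) + [str(c) for c in pop.gmap.chrom])
        w.writerow(["", ""] + [""] * len(pheno_cols) + [f"{p:.6g}" for p in pop.gmap.pos])
        for i in range(len(pop)):
            row = [str(pop.ids[i]), str(pop.sex[i])]
            for col in pheno_cols:
                v = pop.phenotypes[col].iloc[i]
                row.append(f"{v:.10g}" if isinstance(v, (int, float, np.floating)) else str(v))
            row.extend(_CODE_TO_CHAR[int(g)] for g in pop.genotypes[i])
            w.writerow(row)


def read_cross(path, generation=""):
    """Read a cross CSV file back into a Population.

    Errors cite 1-based line numbers.  Phenotype columns are the header
    columns between ``sex`` and the first marker; marker columns are the
    ones with a chromosome entry on line 2.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 4:
        raise ValueError(f"{path}: need a 3-line header plus at least one individual")
    header, chrom_row, pos_row = rows[0], rows[1], rows[2]
    if header[:2] != ["id", "sex"]:
        raise ValueError(f"{path} line 1: header must start with 'id,sex'")
    if not (len(header) == len(chrom_row) == len(pos_row)):
        raise ValueError(f"{path}: header lines 1-3 have differing column counts")
    marker_cols = [j for j in range(2, len(header)) if chrom_row[j].strip() != ""]
    if not marker_cols:
        raise ValueError(f"{path} line 2: no marker columns (chromosome row is empty)")
    first_marker = marker_cols[0]
    if marker_cols != list(range(first_marker, len(header))):
        raise ValueError(f"{path} line 2: marker columns must be contiguous at the end")
    pheno_cols = header[2:first_marker]
    gmap = GeneticMap(
        names=header[first_marker:],
        chrom=[chrom_row[j].strip() for j in marker_cols],
        pos=[float(pos_row[j]) for j in marker_cols],
    )
    ids, sexes, phenos, genos = [], [], [], []
    seen = set()
    for ln, row in enumerate(rows[3:], start=4):
        if not row or all(c.strip() == "" for c in row):
            continue
        if len(row) != len(header):
            raise ValueError(f"{path} line {ln}: expected {len(header)} fields, got {len(row)}")
        ind = row[0].strip()
        if ind in seen:
            raise ValueError(f"{path} line {ln}: duplicated individual id {ind!r}")
        seen.add(ind)
        ids.append(ind)
        sexes.append(row[1].strip() or "M")
        rec = {}
        for name, val in zip(pheno_cols, row[2:first_marker]):
            try:
                rec[name] = float(val)
            except ValueError:
                rec[name] = val
        phenos.append(rec)
        g = []
        for j in marker_cols:
            ch = row[j].strip()
            if ch not in _CHAR_TO_CODE:
                raise ValueError(
                    f"{path} line {ln}: unknown genotype code {ch!r} in column "
                    f"{header[j]} (expected A/H/B/-)"
                )
            g.append(_CHAR_TO_CODE[ch])
        genos.append(g)
    return Population(
        ids=np.array(ids),
        genotypes=np.array(genos, dtype=np.int8),
        gmap=gmap,
        phenotypes=pd.DataFrame(phenos),
        sex=np.array(sexes, dtype=object),
        generation=generation,
    )


def write_outlines(outlines, path):
    """Write outlines (Raw or Standard) to a long-format coordinate table."""
    rows = []
    for o in outlines:
        for i, (x, y) in enumerate(np.asarray(o.points)):
            rows.append(
                {
                    "outline_id": o.outline_id,
                    "point_index": i,
                    "x": x,
                    "y": y,
                    "side": getattr(o, "side", ""),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_outlines(path):
    """Read a coordinate table into a list of RawOutline (trace order kept)."""
    tab = pd.read_csv(path)
    need = {"outline_id", "point_index", "x", "y"}
    if not need.issubset(tab.columns):
        raise ValueError(f"{path}: outline files need columns {sorted(need)}")
    out = []
    for oid, sub in tab.groupby("outline_id", sort=False):
        sub = sub.sort_values("point_index")
        side = str(sub["side"].iloc[0]) if "side" in sub.columns else "left"
        out.append(
            RawOutline(
                points=sub[["x", "y"]].to_numpy(dtype=float),
                outline_id=str(oid),
                side=side,
            )
        )
    return out


def read_candidates(path):
    """Candidate-locus table: columns name, chrom, pos (cM)."""
    tab = pd.read_csv(path)
    need = {"name", "chrom", "pos"}
    if not need.issubset(tab.columns):
        raise ValueError(f"{path}: candidate files need columns {sorted(need)}")
    return CandidateSet.from_frame(tab)


def write_candidates(candidates, path):
    candidates.to_frame().to_csv(path, index=False)
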