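"""Shared containers for cross data: genetic maps and mapping populations.

Genotypes are stored as small integers throughout:

====  =========================================================
code  meaning
====  =========================================================
0     homozygous for the A (b3852-like) allele; hemizygous A on
      the male X
1     heterozygous (autosomes only)
2     homozygous B (Sam-like); hemizygous B on the male X
-1    missing
====  =========================================================

All phenotyped individuals are male (the trait is male-specific), so X
genotypes only ever take the hemizygous codes 0 and 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GENO_AA = 0
GENO_AB = 1
GENO_BB = 2
MISSING = -1

#: Female-meiosis map length (cM) of each chromosome arm carrying markers.
#: Chromosome 4 is deliberately absent: it is essentially non-recombining
#: and is outside the scope of this package.
ARM_LENGTHS = {"X": 66.0, "2L": 55.0, "2R": 52.0, "3L": 47.0, "3R": 63.0}

#: Offset of each arm's origin on its chromosome's cM coordinate.
ARM_OFFSETS = {"X": 0.0, "2L": 0.0, "2R": 55.0, "3L": 0.0, "3R": 47.0}

ARM_TO_CHROM = {"X": "X", "2L": "2", "2R": "2", "3L": "3", "3R": "3"}

CHROMOSOMES = ("X", "2", "3")


def haldane_r(d_cm):
    """Recombination fraction for a map distance in cM (Haldane, no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def haldane_cm(r):
    """Inverse Haldane map function: distance in cM for a recombination fraction."""
    r = np.asarray(r, dtype=float)
    return -50.0 * np.log(1.0 - 2.0 * r)


@dataclass(frozen=True)
class GeneticMap:
    """An ordered marker map over the X and the two major autosomes.

    Parameters
    ----------
    names : marker names, unique.
    chrom : chromosome of each marker, one of ``{"X", "2", "3"}``.
    pos : map position in cM.  Interpreted as female-meiosis distance for
        simulation input maps; maps estimated from cross genotypes come out
        on a sex-averaged scale (see docs/methods.md).
    arm : chromosome-arm annotation (``X, 2L, 2R, 3L, 3R``) used for
        reporting; inferred positions never depend on it.
    """

    names: tuple
    chrom: np.ndarray
    pos: np.ndarray
    arm: np.ndarray = None

    def __post_init__(self):
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "chrom", np.asarray(self.chrom, dtype=object))
        object.__setattr__(self, "pos", np.asarray(self.pos, dtype=float))
        if self.arm is None:
            object.__setattr__(self, "arm", self.chrom.copy())
        else:
            object.__setattr__(self, "arm", np.asarray(self.arm, dtype=object))
        if len(set(self.names)) != len(self.names):
            raise ValueError("marker names must be unique")
        if any(c == "4" for c in self.chrom):
            raise ValueError(
                "chromosome 4 markers are not supported: the dot chromosome is "
                "essentially non-recombining and outside the scope of this package"
            )
        bad = set(self.chrom) - set(CHROMOSOMES)
        if bad:
            raise ValueError(f"unknown chromosome(s): {sorted(bad)}")
        for c in self.chromosomes():
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"marker positions must be nondecreasing on chromosome {c}")

    def __len__(self):
        return len(self.names)

    def chromosomes(self):
        """Chromosomes present, in canonical X, 2, 3 order."""
        present = set(self.chrom)
        return [c for c in CHROMOSOMES if c in present]

    def index_on(self, chrom):
        """Indices of markers on one chromosome, in map order."""
        return np.flatnonzero(self.chrom == chrom)

    def is_x(self):
        return self.chrom == "X"

    def chrom_length(self, chrom):
        idx = self.index_on(chrom)
        p = self.pos[idx]
        return float(p[-1] - p[0]) if len(p) else 0.0

    def total_length(self, chromosomes=None):
        """Summed map length over the given chromosomes (default: all present)."""
        if chromosomes is None:
            chromosomes = self.chromosomes()
        return float(sum(self.chrom_length(c) for c in chromosomes))

    def to_frame(self):
        return pd.DataFrame(
            {"marker": list(self.names), "chrom": self.chrom, "arm": self.arm, "pos": self.pos}
        )


@dataclass
class Population:
    """A phenotyped (all-male) mapping population with marker genotypes.

    ``genotypes`` is an ``(n_individuals, n_markers)`` int8 array using the
    module-level codes.  ``genotyped`` flags individuals with any observed
    genotype; under selective genotyping, non-tail individuals have every
    genotype missing but keep their phenotypes.  ``qtl_loci`` /
    ``qtl_genotypes`` carry simulated genotypes at trait loci that are not
    markers (they exist only for synthetic populations and are never used
    by the inference code).
    """

    ids: np.ndarray
    genotypes: np.ndarray
    gmap: GeneticMap
    phenotypes: pd.DataFrame
    sex: np.ndarray = None
    genotyped: np.ndarray = None
    generation: str = ""
    qtl_loci: list = field(default_factory=list)
    qtl_genotypes: np.ndarray = None

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n = len(self.ids)
        if self.genotypes.shape != (n, len(self.gmap)):
            raise ValueError("genotype matrix shape does not match ids x markers")
        if self.sex is None:
            self.sex = np.full(n, "M", dtype=object)
        if self.genotyped is None:
            self.genotyped = (self.genotypes != MISSING).any(axis=1)
        self.genotyped = np.asarray(self.genotyped, dtype=bool)
        if len(self.phenotypes) != n:
            raise ValueError("phenotype table length does not match ids")
        x_cols = self.gmap.is_x()
        male = self.sex == "M"
        if np.any(self.genotypes[np.ix_(male, x_cols)] == GENO_AB):
            raise ValueError("male X genotypes must be hemizygous (codes 0/2), got a heterozygote")

    def __len__(self):
        return len(self.ids)

    @property
    def n_genotyped(self):
        return int(self.genotyped.sum())

    def phenotype(self, name):
        if name not in self.phenotypes.columns:
            raise KeyError(f"phenotype {name!r} not present (have {list(self.phenotypes.columns)})")
        y = self.phenotypes[name].to_numpy(dtype=float)
        if np.any(~np.isfinite(y)):
            raise ValueError(f"phenotype {name!r} contains non-finite values")
        return y

    def with_phenotypes(self, frame):
        """Return a copy with phenotype columns added/replaced."""
        pheno = self.phenotypes.copy()
        for col in frame.columns:
            pheno[col] = np.asarray(frame[col])
        return replace(self, phenotypes=pheno)

    def subset(self, mask):
        """Row subset (boolean mask or index array) as a new Population."""
        mask = np.asarray(mask)
        return Population(
            ids=self.ids[mask],
            genotypes=self.genotypes[mask],
            gmap=self.gmap,
            phenotypes=self.phenotypes.iloc[np.flatnonzero(mask) if mask.dtype == bool else mask].reset_index(drop=True),
            sex=self.sex[mask],
            genotyped=self.genotyped[mask],
            generation=self.generation,
            qtl_loci=list(self.qtl_loci),
            qtl_genotypes=None if self.qtl_genotypes is None else self.qtl_genotypes[mask],
        )

    def locus_genotypes(self, chrom, pos, tol=1e-6):
        """Genotypes at a locus, looked up among markers then simulated trait loci."""
        on = (self.gmap.chrom == chrom) & (np.abs(self.gmap.pos - pos) < tol)
        if on.any():
            return self.genotypes[:, np.flatnonzero(on)[0]]
        for j, (c, p) in enumerate(self.qtl_loci):
            if c == chrom and abs(p - pos) < tol:
                return self.qtl_genotypes[:, j]
        raise KeyError(f"no simulated genotypes at {chrom}:{pos} (not a marker or a stored trait locus)")


def interpolate_position(map_from, map_to, chrom, pos):
    """Carry a chromosome position from one map to another by piecewise-linear
    interpolation between shared markers (clamped to the terminal markers).

    Used to express, e.g., a position on the reference map on an expanded
    estimated map.
    """
    if tuple(map_from.names) != tuple(map_to.names):
        raise ValueError("maps must share the same markers to convert positions")
    idx = map_from.index_on(chrom)
    if len(idx) == 0:
        raise KeyError(f"chromosome {chrom!r} has no markers")
    p_from = map_from.pos[idx]
    p_to = map_to.pos[idx]
    return float(np.interp(pos, p_from, p_to))
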