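"""Forward simulator of trioecious XX:XO inheritance with modified X meiosis.

*Auanema rhodensis* has three sexes.  Males are XO and produce only haplo-X
sperm (nullo-X spermatids are discarded), so the X passes strictly from
father to son during outcrossing.  In XX hermaphrodites the X does not
recombine and segregates asymmetrically: oogenesis yields mostly nullo-X
oocytes and spermatogenesis yields diplo-X sperm carrying both maternal X
haplotypes intact.  Selfing therefore produces XX progeny whose X genotype
is an exact copy of the mother's — heterozygosity on the X is conserved
under selfing.  In females the X recombines normally and most oocytes are
haplo-X.

Autosomes follow standard meiosis with Haldane (Poisson, no-interference)
crossovers.

The simulator produces panels of F2 hermaphrodite-derived lines (two fully
homozygous founder strains, APS4 x APS6) mirroring a RAD-seq mapping-panel
design, with optional rare female-mediated generations during line
expansion that let the X recombine and lose heterozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from auanema.io import GenotypeMatrix

__all__ = [
    "Chromosome",
    "MarkerMap",
    "GameteRules",
    "Individual",
    "Gamete",
    "default_marker_map",
    "make_gamete",
    "cross",
    "self_cross",
    "simulate_f2_panel",
    "genotype_frequencies",
]

Sex = Literal["male", "female", "hermaphrodite"]

ALLELE_NAMES = ("APS4", "APS6")  # allele 0, allele 1


@dataclass(frozen=True)
class Chromosome:
    name: str
    is_x: bool
    length_cm: float
    marker_ids: tuple[str, ...]
    positions_cm: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.marker_ids) != len(self.positions_cm):
            raise ValueError("marker/position length mismatch")
        pos = np.asarray(self.positions_cm)
        if pos.size and (np.diff(pos) < 0).any():
            raise ValueError(f"positions not nondecreasing on {self.name}")


@dataclass(frozen=True)
class MarkerMap:
    """Chromosome layout with marker positions in centimorgans."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        n_x = sum(c.is_x for c in self.chromosomes)
        if n_x != 1:
            raise ValueError(f"exactly one X chromosome required, got {n_x}")

    @property
    def x(self) -> Chromosome:
        return next(c for c in self.chromosomes if c.is_x)

    @property
    def autosomes(self) -> tuple[Chromosome, ...]:
        return tuple(c for c in self.chromosomes if not c.is_x)


def default_marker_map(
    n_autosomes: int = 6,
    markers_per_autosome: int = 150,
    x_markers: int = 92,
    length_cm: float = 50.0,
) -> MarkerMap:
    """Seven-chromosome layout: six autosomes plus one X.

    Markers are evenly spaced on each chromosome.  Defaults echo the scale
    of the published RAD map (1,052 markers over 7 linkage groups, 92 on
    the X).
    """
    chroms = []
    for i in range(n_autosomes):
        name = f"LG{i + 1 if i < 4 else i + 2}"  # LG1..LG4, LG6, LG7
        pos = tuple(np.linspace(0, length_cm, markers_per_autosome))
        ids = tuple(f"{name}_m{j:03d}" for j in range(markers_per_autosome))
        chroms.append(Chromosome(name, False, length_cm, ids, pos))
    xpos = tuple(np.linspace(0, length_cm, x_markers))
    xids = tuple(f"LG5X_m{j:03d}" for j in range(x_markers))
    chroms.insert(4, Chromosome("LG5X", True, length_cm, xids, xpos))
    return MarkerMap(tuple(chroms))


@dataclass(frozen=True)
class GameteRules:
    """Transmission rules for gametogenesis.

    ``p_herm_oocyte_haploX``: probability a hermaphrodite oocyte carries one
    X (otherwise nullo-X).  ``p_female_oocyte_nulloX``: probability a female
    oocyte carries no X (otherwise one recombined X).  X recombination is
    off in hermaphrodites and on in females by default, matching the
    chromosome-wide absence of hermaphrodite X crossovers.
    """

    p_herm_oocyte_haploX: float = 0.05
    p_female_oocyte_nulloX: float = 0.05
    x_recombination_in_hermaphrodites: bool = False
    x_recombination_in_females: bool = True

    def __post_init__(self) -> None:
        for p in (self.p_herm_oocyte_haploX, self.p_female_oocyte_nulloX):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass(frozen=True)
class Individual:
    """A simulated nematode.

    ``autosomes`` maps chromosome name -> (2, n_markers) int8 array of
    alleles (0 = APS4, 1 = APS6).  ``x_haplotypes`` holds 1 (males) or 2
    (females/hermaphrodites) allele vectors.
    """

    sex: Sex
    autosomes: dict[str, np.ndarray]
    x_haplotypes: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        n = len(self.x_haplotypes)
        if self.sex == "male" and n != 1:
            raise ValueError("males carry exactly 1 X haplotype")
        if self.sex in ("female", "hermaphrodite") and n != 2:
            raise ValueError(f"{self.sex}s carry exactly 2 X haplotypes")


@dataclass(frozen=True)
class Gamete:
    autosomes: dict[str, np.ndarray]  # one haplotype per autosome
    x_haplotypes: tuple[np.ndarray, ...]  # 0, 1 or 2 vectors

    @property
    def n_x(self) -> int:
        return len(self.x_haplotypes)


def _meiosis_haplotype(
    hap_pair: np.ndarray, positions_cm: Sequence[float], rng: np.random.Generator
) -> np.ndarray:
    """One meiotic product under the Haldane model.

    Crossover count is Poisson(length in Morgans) on the marker interval;
    crossover points are uniform; the starting parental strand is random.
    """
    pos = np.asarray(positions_cm, dtype=float)
    if pos.size == 0:
        return np.empty(0, dtype=np.int8)
    span_m = (pos[-1] - pos[0]) / 100.0
    n_co = rng.poisson(span_m)
    strand = np.full(pos.size, rng.integers(2))
    if n_co:
        points = rng.uniform(pos[0], pos[-1], size=n_co)
        for p in points:
            strand[pos > p] ^= 1
    return hap_pair[strand, np.arange(pos.size)].astype(np.int8)


def make_gamete(
    parent: Individual,
    kind: Literal["oocyte", "sperm"],
    marker_map: MarkerMap,
    rules: GameteRules | None = None,
    rng: np.random.Generator | None = None,
) -> Gamete:
    """Draw one gamete from ``parent`` under the X transmission rules.

    Autosomes always undergo standard meiosis.  X content by parent and
    gamete type: hermaphrodite oocytes are mostly nullo-X; hermaphrodite
    sperm carry both X haplotypes intact (diplo-X); female oocytes carry
    one recombined X (rarely nullo-X); male sperm always carry the single
    paternal X.
    """
    rules = rules or GameteRules()
    rng = rng if rng is not None else np.random.default_rng()
    if kind == "sperm" and parent.sex == "female":
        raise ValueError("females do not produce sperm")
    if kind == "oocyte" and parent.sex == "male":
        raise ValueError("males do not produce oocytes")

    autos = {
        chrom.name: _meiosis_haplotype(
            parent.autosomes[chrom.name], chrom.positions_cm, rng
        )
        for chrom in marker_map.autosomes
    }
    xc = marker_map.x
    xh: tuple[np.ndarray, ...]
    if parent.sex == "male":
        xh = (parent.x_haplotypes[0].copy(),)
    elif parent.sex == "hermaphrodite":
        if kind == "sperm":
            if rules.x_recombination_in_hermaphrodites:
                pair = np.stack(parent.x_haplotypes)
                xh = (
                    _meiosis_haplotype(pair, xc.positions_cm, rng),
                    _meiosis_haplotype(pair, xc.positions_cm, rng),
                )
            else:
                xh = tuple(h.copy() for h in parent.x_haplotypes)  # diplo-X
        else:  # oocyte: mostly nullo-X
            if rng.random() < rules.p_herm_oocyte_haploX:
                if rules.x_recombination_in_hermaphrodites:
                    pair = np.stack(parent.x_haplotypes)
                    xh = (_meiosis_haplotype(pair, xc.positions_cm, rng),)
                else:
                    xh = (parent.x_haplotypes[rng.integers(2)].copy(),)
            else:
                xh = ()
    else:  # female oocyte
        if rng.random() < rules.p_female_oocyte_nulloX:
            xh = ()
        else:
            pair = np.stack(parent.x_haplotypes)
            if rules.x_recombination_in_females:
                xh = (_meiosis_haplotype(pair, xc.positions_cm, rng),)
            else:
                xh = (pair[rng.integers(2)].copy(),)
    return Gamete(autos, xh)


@dataclass(frozen=True)
class SexParams:
    """Sexing of XX zygotes and handling of aneuploid X counts.

    ``p_herm_given_xx`` is context-dependent in the animal (brood sex
    ratios vary with cross type and maternal age); 0.5 is a neutral
    default.  Triplo-X zygotes are redrawn by default; set
    ``triplo_x="female"`` to instead keep them as XX-like females.
    """

    p_herm_given_xx: float = 0.5
    triplo_x: Literal["redraw", "female"] = "redraw"


def cross(
    mother: Individual,
    father: Individual | None,
    marker_map: MarkerMap,
    rules: GameteRules | None = None,
    sex_params: SexParams | None = None,
    rng: np.random.Generator | None = None,
    max_redraws: int = 1000,
) -> Individual:
    """Produce one viable offspring from mother x father (father=None: selfing).

    Nullo-X zygotes (0 X) are inviable and redrawn.  1 X -> male; 2 X ->
    hermaphrodite with probability ``p_herm_given_xx``, else female.
    Triplo-X zygotes are redrawn (or kept as females, configurable).
    """
    rules = rules or GameteRules()
    sex_params = sex_params or SexParams()
    rng = rng if rng is not None else np.random.default_rng()
    if father is not None and mother.sex == "male":
        raise ValueError("mother must be female or hermaphrodite")
    if father is not None and father.sex != "male":
        raise ValueError("father must be male (or None for selfing)")
    if father is None and mother.sex != "hermaphrodite":
        raise ValueError("only hermaphrodites self-fertilize")

    sperm_source = father if father is not None else mother
    for _ in range(max_redraws):
        oocyte = make_gamete(mother, "oocyte", marker_map, rules, rng)
        sperm = make_gamete(sperm_source, "sperm", marker_map, rules, rng)
        n_x = oocyte.n_x + sperm.n_x
        if n_x == 0:
            continue  # inviable
        if n_x == 3 and sex_params.triplo_x == "redraw":
            continue
        autos = {
            name: np.stack([oocyte.autosomes[name], sperm.autosomes[name]])
            for name in oocyte.autosomes
        }
        xh = oocyte.x_haplotypes + sperm.x_haplotypes
        if n_x == 1:
            return Individual("male", autos, xh)
        if n_x == 3:  # keep as female, dropping one X at random
            keep = sorted(rng.choice(3, size=2, replace=False))
            xh = (xh[keep[0]], xh[keep[1]])
            return Individual("female", autos, xh)
        sex: Sex = (
            "hermaphrodite"
            if rng.random() < sex_params.p_herm_given_xx
            else "female"
        )
        return Individual(sex, autos, xh)
    raise RuntimeError("no viable zygote after maximum redraws")


def self_cross(
    mother: Individual,
    marker_map: MarkerMap,
    rules: GameteRules | None = None,
    sex_params: SexParams | None = None,
    rng: np.random.Generator | None = None,
) -> Individual:
    """Self-fertilization of a hermaphrodite."""
    return cross(mother, None, marker_map, rules, sex_params, rng)


def _founder(marker_map: MarkerMap, allele: int, sex: Sex) -> Individual:
    autos = {
        c.name: np.full((2, len(c.marker_ids)), allele, dtype=np.int8)
        for c in marker_map.autosomes
    }
    nx = 1 if sex == "male" else 2
    xvec = np.full(len(marker_map.x.marker_ids), allele, dtype=np.int8)
    return Individual(sex, autos, tuple(xvec.copy() for _ in range(nx)))


def _force_sex(ind: Individual, sex: Sex) -> Individual:
    """Relabel an XX individual's somatic sex (female <-> hermaphrodite).

    Sexual fate of XX animals is developmental (dauer-passage dependent),
    not genotypic, so relabeling is legitimate when a specific XX morph is
    needed from a brood.
    """
    if len(ind.x_haplotypes) != 2:
        raise ValueError("can only relabel XX individuals")
    return replace(ind, sex=sex)


def _sibling_male(
    mother: Individual,
    marker_map: MarkerMap,
    rules: GameteRules,
    rng: np.random.Generator,
) -> Individual:
    """A rare male from a selfing hermaphrodite brood.

    Males from selfing require the uncommon haplo-X oocyte to meet a
    nullo-X sperm; that sperm class is not produced under the default
    rules, so the male is constructed directly: selfed autosomal meiosis
    products plus one maternal X haplotype chosen at random.
    """
    oocyte = make_gamete(mother, "oocyte", marker_map, rules, rng)
    sperm = make_gamete(mother, "sperm", marker_map, rules, rng)
    autos = {
        name: np.stack([oocyte.autosomes[name], sperm.autosomes[name]])
        for name in oocyte.autosomes
    }
    x = mother.x_haplotypes[rng.integers(2)].copy()
    return Individual("male", autos, (x,))


def _xx_child(
    mother: Individual,
    father: Individual | None,
    marker_map: MarkerMap,
    rules: GameteRules,
    sex_params: SexParams,
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> Individual:
    """First XX offspring of a cross (line propagation needs XX morphs)."""
    for _ in range(max_tries):
        child = cross(mother, father, marker_map, rules, sex_params, rng)
        if len(child.x_haplotypes) == 2:
            return child
    raise RuntimeError("no XX offspring after maximum tries")


def simulate_f2_panel(
    marker_map: MarkerMap | None = None,
    n_lines: int = 95,
    expansion_generations: tuple[int, int] = (3, 10),
    p_female_generation: float = 0.05,
    missing_rate: float = 0.0,
    rules: GameteRules | None = None,
    sex_params: SexParams | None = None,
    seed: int | np.random.Generator = 0,
) -> GenotypeMatrix:
    """Simulate a panel of F2 hermaphrodite-derived lines.

    Design: P0 = homozygous APS4 female x homozygous APS6 male; F1
    hermaphrodites self; each line is founded by a single F2 hermaphrodite
    and propagated by single-individual selfing for g ~ Uniform{range}
    generations.  Each expansion generation is independently replaced by a
    female x sibling-male cross with probability ``p_female_generation``,
    which lets the X recombine and become homozygous.  One individual per
    line is genotyped at every marker; calls are masked at
    ``missing_rate``.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    lo, hi = expansion_generations
    if not (0 <= lo <= hi):
        raise ValueError("invalid expansion_generations range")
    marker_map = marker_map or default_marker_map()
    rules = rules or GameteRules()
    sex_params = sex_params or SexParams()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    p0_mother = _founder(marker_map, 0, "female")
    p0_father = _founder(marker_map, 1, "male")

    lines = []
    for _ in range(n_lines):
        f1 = _xx_child(p0_mother, p0_father, marker_map, rules, sex_params, rng)
        f1 = _force_sex(f1, "hermaphrodite")
        f2 = self_cross(f1, marker_map, rules, sex_params, rng)
        current = _force_sex(f2, "hermaphrodite")
        g = int(rng.integers(lo, hi + 1))
        for _ in range(g):
            if rng.random() < p_female_generation:
                mother_f = _force_sex(
                    self_cross(current, marker_map, rules, sex_params, rng),
                    "female",
                )
                father_m = _sibling_male(current, marker_map, rules, rng)
                child = _xx_child(
                    mother_f, father_m, marker_map, rules, sex_params, rng
                )
            else:
                child = self_cross(current, marker_map, rules, sex_params, rng)
            current = _force_sex(child, "hermaphrodite")
        lines.append(current)

    marker_ids: list[str] = []
    marker_locs: dict[str, tuple[str, float]] = {}
    for c in marker_map.chromosomes:
        for mid, pos in zip(c.marker_ids, c.positions_cm):
            marker_ids.append(mid)
            marker_locs[mid] = (c.name, float(pos))

    code_of = np.array(["AA", "AB", "BB"])
    rows = []
    for ind in lines:
        parts = []
        for c in marker_map.chromosomes:
            if c.is_x:
                dose = ind.x_haplotypes[0] + ind.x_haplotypes[1]
            else:
                dose = ind.autosomes[c.name].sum(axis=0)
            parts.append(code_of[dose])
        rows.append(np.concatenate(parts))
    codes = np.array(rows, dtype="<U2")
    if missing_rate > 0:
        mask = rng.random(codes.shape) < missing_rate
        codes[mask] = "NA"

    line_ids = tuple(f"F2L{i + 1:03d}" for i in range(n_lines))
    return GenotypeMatrix(line_ids, tuple(marker_ids), codes, marker_locs)


def genotype_frequencies(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-chromosome genotype frequencies pooled over markers and lines.

    Returns columns (chromosome, freq_AA, freq_AB, freq_BB, n_markers);
    frequencies are over non-missing calls and sum to 1 per chromosome.
    """
    if gm.n_markers == 0 or gm.n_lines == 0:
        raise ValueError("empty genotype matrix")
    chroms = gm.marker_chromosomes()
    records = []
    for chrom in pd.unique(chroms):
        sub = gm.codes[:, chroms == chrom]
        n_obs = (sub != "NA").sum()
        if n_obs == 0:
            freqs = (np.nan, np.nan, np.nan)
        else:
            freqs = tuple((sub == g).sum() / n_obs for g in ("AA", "AB", "BB"))
        records.append((chrom, *freqs, int((chroms == chrom).sum())))
    return pd.DataFrame(
        records,
        columns=["chromosome", "freq_AA", "freq_AB", "freq_BB", "n_markers"],
    )
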