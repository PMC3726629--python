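"""Forward-time simulator of the compound-X (DX) transmission scheme.

In *Drosophila*, a female carrying a compound X (two X chromosomes attached
at the centromere) plus a Y produces only two viable zygote classes when
crossed to a wildtype male: sons that receive their father's X and their
mother's Y, and compound-X daughters that receive their father's Y.  Triple-X
and YY zygotes die.  This forces father-to-son transmission of the X, so a
population propagated through DX mothers exposes its X chromosomes to
selection in males only (the MLX regime), while a control population keeps
ordinary XX/XY inheritance.

The X carries ``L`` biallelic sexually antagonistic loci; allele 1 is
male-benefit / female-detriment.  Fitness is multiplicative:

    male:    w = (1 + s_male)^(number of 1-alleles on the single X)
    female:  w = (1 - s_female)^(allele count across both X / 2)

(semidominant female cost).  Paternity and maternity are sampled in
proportion to fitness, abstracting the vial mating ecology into fitness-
proportional parentage — fitness in the source experiment is measured
exactly as paternity share.

A "recombination box" (RB) of wildtype females runs alongside each MLX
population: each generation a fixed number of MLX males breed in the RB and
the same number of RB-bred males return to the main population, so X
chromosomes keep recombining instead of evolving clonally.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class Karyotype(enum.Enum):
    WILDTYPE_MALE = "wildtype_male"  # X, Y
    WILDTYPE_FEMALE = "wildtype_female"  # X, X
    DX_FEMALE = "dx_female"  # compound X (XX) + Y


@dataclass
class Individual:
    """One fly: karyotype, X haplotype(s) over L loci, and a Y lineage tag.

    ``x_haplotypes`` holds one array (uint8, 0/1 per locus) for a wildtype
    male, two for a wildtype female, and two for a DX female (the compound X
    is transmitted as a unit).  ``y_tag`` identifies the Y lineage (None for
    wildtype females).
    """

    karyotype: Karyotype
    x_haplotypes: tuple[np.ndarray, ...]
    y_tag: int | None = None

    def __post_init__(self):
        n_x = len(self.x_haplotypes)
        expect = 1 if self.karyotype is Karyotype.WILDTYPE_MALE else 2
        if n_x != expect:
            raise ValueError(
                f"{self.karyotype.value} must carry {expect} X haplotype(s), got {n_x}"
            )
        has_y = self.y_tag is not None
        if self.karyotype is Karyotype.WILDTYPE_FEMALE and has_y:
            raise ValueError("wildtype female cannot carry a Y")
        if self.karyotype in (Karyotype.WILDTYPE_MALE, Karyotype.DX_FEMALE) and not has_y:
            raise ValueError(f"{self.karyotype.value} must carry a Y (y_tag)")


def male_fitness(h: np.ndarray, s_male: float) -> float:
    """Multiplicative fitness of a hemizygous male X: (1 + s)^(#alleles)."""
    if not 0 <= s_male < 1:
        raise ValueError("s_male must be in [0, 1)")
    return float((1.0 + s_male) ** int(np.sum(h)))

def female_fitness(h1: np.ndarray, h2: np.ndarray, s_female: float) -> float:
    """Semidominant female fitness: (1 - s)^(allele count across both X / 2)."""
    if not 0 <= s_female < 1:
        raise ValueError("s_female must be in [0, 1)")
    return float((1.0 - s_female) ** ((int(np.sum(h1)) + int(np.sum(h2))) / 2.0))


def _recombine(h1: np.ndarray, h2: np.ndarray, rate: float, rng) -> np.ndarray:
    """One recombinant gamete from a haplotype pair (rate per adjacent pair)."""
    L = h1.shape[0]
    start = int(rng.integers(2))
    if rate <= 0 or L == 1:
        return (h1 if start == 0 else h2).copy()
    cross = rng.random(L - 1) < rate
    chooser = np.empty(L, dtype=int)
    chooser[0] = start
    chooser[1:] = (start + np.cumsum(cross)) % 2
    return np.where(chooser == 0, h1, h2).astype(np.uint8)


def cross_dx(
    father: Individual, mother: Individual, n_offspring: int, rng
) -> list[Individual]:
    """Cross a wildtype male to a DX female; return the viable offspring.

    ``n_offspring`` is the number of zygotes formed.  Each zygote combines a
    random paternal gamete (X or Y) with a random maternal egg (compound X or
    Y).  Paternal X x maternal Y -> son carrying the father's X unchanged and
    the mother's Y; paternal Y x maternal compound X -> DX daughter carrying
    the father's Y.  Triple-X and YY zygotes are discarded as inviable, so
    each surviving class has expected zygote frequency 1/2.
    """
    if father.karyotype is not Karyotype.WILDTYPE_MALE:
        raise ValueError("cross_dx father must be a wildtype male")
    if mother.karyotype is not Karyotype.DX_FEMALE:
        raise ValueError("cross_dx mother must be a DX female")
    if n_offspring < 0:
        raise ValueError("n_offspring must be >= 0")
    paternal_x = rng.random(n_offspring) < 0.5  # else paternal Y
    maternal_y = rng.random(n_offspring) < 0.5  # else compound-X egg
    offspring: list[Individual] = []
    for px, my in zip(paternal_x, maternal_y):
        if px and my:  # son: father's X + mother's Y
            offspring.append(
                Individual(
                    Karyotype.WILDTYPE_MALE,
                    (father.x_haplotypes[0].copy(),),
                    y_tag=mother.y_tag,
                )
            )
        elif not px and not my:  # DX daughter: mother's compound X + father's Y
            offspring.append(
                Individual(
                    Karyotype.DX_FEMALE,
                    tuple(h.copy() for h in mother.x_haplotypes),
                    y_tag=father.y_tag,
                )
            )
        # paternal X + compound-X egg (triple X) and paternal Y + Y egg (YY)
        # are inviable and yield nothing.
    return offspring


def cross_wildtype(
    father: Individual,
    mother: Individual,
    n_offspring: int,
    recombination_rate: float,
    rng,
) -> list[Individual]:
    """Standard XX x XY cross with maternal recombination.

    Daughters receive the father's X plus one recombinant maternal X; sons
    receive a recombinant maternal X plus the father's Y.  ``n_offspring``
    zygotes, all viable.
    """
    if father.karyotype is not Karyotype.WILDTYPE_MALE:
        raise ValueError("cross_wildtype father must be a wildtype male")
    if mother.karyotype is not Karyotype.WILDTYPE_FEMALE:
        raise ValueError("cross_wildtype mother must be a wildtype female")
    if n_offspring < 0:
        raise ValueError("n_offspring must be >= 0")
    offspring: list[Individual] = []
    for _ in range(n_offspring):
        egg = _recombine(*mother.x_haplotypes, recombination_rate, rng)
        if rng.random() < 0.5:  # son
            offspring.append(
                Individual(Karyotype.WILDTYPE_MALE, (egg,), y_tag=father.y_tag)
            )
        else:  # daughter
            offspring.append(
                Individual(
                    Karyotype.WILDTYPE_FEMALE,
                    (father.x_haplotypes[0].copy(), egg),
                )
            )
    return offspring


@dataclass
class SimParams:
    """Parameters of one simulation run.

    ``N_main`` is the total main-population size (half males); the source
    protocol used 640 with 32 males exchanged with the RB each generation.
    ``mode`` is "MLX" (DX-mothered main population + RB) or "Control"
    (wildtype breeding throughout, no RB).
    """

    L: int = 20
    s_male: float = 0.0
    s_female: float = 0.0
    init_freq: float = 0.5
    N_main: int = 640
    N_rb: int = 32
    migrants_per_gen: int = 32
    generations: int = 40
    recombination_rate: float = 0.5
    rb_selection: bool = True
    mode: str = "MLX"
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("MLX", "Control"):
            raise ValueError("mode must be 'MLX' or 'Control'")
        if self.mode == "MLX" and self.migrants_per_gen > 0 and self.N_rb <= 0:
            raise ValueError("migrants_per_gen > 0 requires N_rb > 0")
        if self.N_main < 2 or self.L < 1 or self.generations < 0:
            raise ValueError("invalid population size, locus count or generations")
        if not 0 <= self.init_freq <= 1:
            raise ValueError("init_freq must be in [0, 1]")
        if self.mode == "MLX" and self.migrants_per_gen > min(
            self.N_main // 2, self.N_rb
        ):
            raise ValueError("migrants_per_gen exceeds available males")


def _male_w(X: np.ndarray, s: float) -> np.ndarray:
    return (1.0 + s) ** X.sum(axis=1)


def _female_w(F: np.ndarray, s: float) -> np.ndarray:
    return (1.0 - s) ** (F.sum(axis=(1, 2)) / 2.0)


def _sample_parents(w: np.ndarray, k: int, rng) -> np.ndarray:
    p = w / w.sum()
    return rng.choice(w.shape[0], size=k, replace=True, p=p)


def _recombine_rows(F: np.ndarray, rate: float, rng) -> np.ndarray:
    """Vectorized maternal gametes: one recombinant per haplotype pair."""
    k, _, L = F.shape
    start = rng.integers(2, size=k)
    if rate <= 0 or L == 1:
        chooser = np.broadcast_to(start[:, None], (k, L))
    else:
        cross = rng.random((k, L - 1)) < rate
        chooser = np.empty((k, L), dtype=np.int64)
        chooser[:, 0] = start
        chooser[:, 1:] = (start[:, None] + np.cumsum(cross, axis=1)) % 2
    rows = np.arange(k)[:, None]
    return F[rows, chooser, np.arange(L)[None, :]]


def run_simulation(params: SimParams) -> pd.DataFrame:
    """Run one replicate; return a per-generation trajectory table.

    Columns: ``generation, mode, allele_freq`` (mean male-benefit allele
    frequency on main-population male X chromosomes), ``mean_male_fitness``
    and ``mean_female_fitness`` (Control females, or RB females under MLX;
    NaN when no wildtype females exist).  Generation 0 is the founding state.

    Internally the population is held as 0/1 haplotype arrays and bred with
    the same gamete rules as :func:`cross_dx` / :func:`cross_wildtype`; under
    MLX every main-population son's X is an exact copy of his father's, and
    only the recombination-box (RB) males reintroduce recombinant X's.
    """
    rng = np.random.default_rng(params.seed)
    n_males = params.N_main // 2
    n_females = params.N_main - n_males

    def init_hap(n):
        return (rng.random((n, params.L)) < params.init_freq).astype(np.uint8)

    M = init_hap(n_males)  # male X haplotypes, main population
    records = []

    if params.mode == "Control":
        F = np.stack([init_hap(n_females), init_hap(n_females)], axis=1)
        for gen in range(params.generations + 1):
            wm, wf = _male_w(M, params.s_male), _female_w(F, params.s_female)
            records.append((gen, "Control", M.mean(), wm.mean(), wf.mean()))
            if gen == params.generations:
                break
            # Sons carry a recombinant maternal X; daughters the paternal X
            # plus a recombinant maternal X (standard XY segregation).
            son_mothers = _sample_parents(wf, n_males, rng)
            dau_fathers = _sample_parents(wm, n_females, rng)
            dau_mothers = _sample_parents(wf, n_females, rng)
            M_next = _recombine_rows(F[son_mothers], params.recombination_rate, rng)
            dau_eggs = _recombine_rows(
                F[dau_mothers], params.recombination_rate, rng
            )
            F = np.stack([M[dau_fathers], dau_eggs], axis=1)
            M = M_next
    else:  # MLX
        use_rb = params.N_rb > 0 and params.migrants_per_gen > 0
        if params.N_rb > 0:
            RBm = init_hap(params.N_rb)
            RBf = np.stack(
                [init_hap(params.N_rb), init_hap(params.N_rb)], axis=1
            )
        else:
            RBm = RBf = None
        for gen in range(params.generations + 1):
            wm = _male_w(M, params.s_male)
            wf_mean = (
                _female_w(RBf, params.s_female).mean() if RBf is not None else np.nan
            )
            records.append((gen, "MLX", M.mean(), wm.mean(), wf_mean))
            if gen == params.generations:
                break
            if use_rb:
                # Exchange: migrants_per_gen males leave for the RB; the
                # previous generation's RB-bred males join the main pool.
                out_idx = rng.choice(
                    n_males, size=params.migrants_per_gen, replace=False
                )
                migrants = M[out_idx]
                keep = np.ones(n_males, dtype=bool)
                keep[out_idx] = False
                pool = np.concatenate([M[keep], RBm], axis=0)
            else:
                pool = M
            # Main population breeds through DX mothers: sons inherit the
            # father's X exactly (fitness-proportional paternity).
            fathers = _sample_parents(_male_w(pool, params.s_male), n_males, rng)
            M_next = pool[fathers].copy()
            if use_rb:
                # RB breeds wildtype: migrant fathers x RB females.
                if params.rb_selection:
                    f_idx = _sample_parents(
                        _male_w(migrants, params.s_male), 2 * params.N_rb, rng
                    )
                    m_idx = _sample_parents(
                        _female_w(RBf, params.s_female), 2 * params.N_rb, rng
                    )
                else:
                    f_idx = rng.integers(0, migrants.shape[0], size=2 * params.N_rb)
                    m_idx = rng.integers(0, params.N_rb, size=2 * params.N_rb)
                eggs = _recombine_rows(RBf[m_idx], params.recombination_rate, rng)
                RBm = eggs[: params.N_rb]  # RB sons: recombinant maternal X
                RBf = np.stack(
                    [migrants[f_idx[params.N_rb :]], eggs[params.N_rb :]], axis=1
                )
            M = M_next

    return pd.DataFrame(
        records,
        columns=[
            "generation",
            "mode",
            "allele_freq",
            "mean_male_fitness",
            "mean_female_fitness",
        ],
    )
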