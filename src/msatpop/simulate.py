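"""Synthetic genotype and sequence data with recorded planted truth.

Population allele frequencies follow the Balding-Nichols construction:
an ancestral frequency vector is drawn from a symmetric Dirichlet and
each population's frequencies from a Dirichlet centered on it with
concentration ``(1 - F) / F``, so the divergence parameter ``F`` equals
the expected F_ST. Genets are drawn under within-population HWE, ramets
copy their genet, and three noise processes can be layered on top:
single-locus somatic mutations (one step of +/- one repeat unit, applied
only to ramets beyond a genet's first so the unmutated reference always
exists), random re-scoring of a single allele call, and missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .genotype import MISSING, GenotypeMatrix, LocusDef, SampleRecord
from .ssr import find_tandem_repeats


def _per_locus(value, n_loci: int, name: str) -> list:
    if isinstance(value, (list, tuple)):
        if len(value) != n_loci:
            raise ValueError(f"{name} must have {n_loci} entries, got {len(value)}")
        return list(value)
    return [value] * n_loci


@dataclass
class SimConfig:
    n_pops: int = 2
    divergence_f: float = 0.08
    n_loci: int = 11
    alleles_per_locus: int | Sequence[int] = 8
    unit_lengths: int | Sequence[int] | None = None  # default: alternate 3/4
    genets_per_pop: int | Sequence[int] = (10, 7)
    samples_per_pop: int | Sequence[int] = (53, 44)
    pop_labels: Sequence[str] | None = None  # default mt-L, mt-S, Pop3...
    p_somatic: float = 0.0
    p_error: float = 0.0
    p_missing: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        for name in ("p_somatic", "p_error", "p_missing"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.divergence_f < 1:
            raise ValueError("divergence_f must be in [0, 1)")
        if self.n_pops < 1 or self.n_loci < 1:
            raise ValueError("need at least one population and one locus")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def resolved(self):
        genets = _per_locus(self.genets_per_pop, self.n_pops, "genets_per_pop")
        samples = _per_locus(self.samples_per_pop, self.n_pops, "samples_per_pop")
        alleles = _per_locus(self.alleles_per_locus, self.n_loci, "alleles_per_locus")
        if self.unit_lengths is None:
            units = [3 if j % 2 == 0 else 4 for j in range(self.n_loci)]
        else:
            units = _per_locus(self.unit_lengths, self.n_loci, "unit_lengths")
        labels = (
            list(self.pop_labels)
            if self.pop_labels is not None
            else (["mt-L", "mt-S"] + [f"Pop{i + 1}" for i in range(2, self.n_pops)])[
                : self.n_pops
            ]
        )
        if any(g < 1 for g in genets):
            raise ValueError("genets_per_pop entries must be >= 1")
        if any(a < 2 for a in alleles):
            raise ValueError("alleles_per_locus entries must be >= 2")
        if any(s < g for s, g in zip(samples, genets)):
            raise ValueError("samples_per_pop must be >= genets_per_pop")
        return genets, samples, alleles, units, labels


@dataclass
class SimTruth:
    """Generating parameters and planted-event coordinates."""

    genet_of_sample: dict[str, str]
    pop_of_sample: dict[str, str]
    allele_sizes: list[np.ndarray]  # per locus, size ladder in bp
    pop_freqs: list[np.ndarray]  # per locus, (n_pops, n_alleles)
    ancestral_freqs: list[np.ndarray]
    mutations: list[tuple[str, str, int, int]] = field(default_factory=list)
    errors: list[tuple[str, str, int, int, int]] = field(default_factory=list)
    missing: list[tuple[str, str]] = field(default_factory=list)

    def n_genets(self) -> int:
        return len(set(self.genet_of_sample.values()))


def simulate_dataset(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw a genotype matrix plus its planted truth; seed-deterministic."""
    rng = np.random.default_rng(config.seed)
    genets, samples_n, alleles_n, units, labels = config.resolved()
    F = config.divergence_f

    # per-locus allele ladders and population frequencies
    allele_sizes: list[np.ndarray] = []
    pop_freqs: list[np.ndarray] = []
    anc_freqs: list[np.ndarray] = []
    loci: list[LocusDef] = []
    for j in range(config.n_loci):
        A, u = alleles_n[j], units[j]
        # keep the ladder plus one mutational step on each side inside [150, 450]
        lo = 150 + u
        hi = 450 - u * (A + 1)
        offset = int(rng.integers(lo, max(lo + 1, hi)))
        allele_sizes.append(offset + u * np.arange(A))
        anc = rng.dirichlet(np.ones(A))
        anc_freqs.append(anc)
        if F > 0:
            conc = (1.0 - F) / F
            pf = np.vstack([rng.dirichlet(anc * conc) for _ in range(config.n_pops)])
        else:
            pf = np.tile(anc, (config.n_pops, 1))
        pop_freqs.append(pf)
        loci.append(LocusDef(locus_id=f"L{j + 1:02d}", unit_length=u))

    samples: list[SampleRecord] = []
    genet_of: dict[str, str] = {}
    pop_of: dict[str, str] = {}
    mutations: list[tuple[str, str, int, int]] = []
    errors: list[tuple[str, str, int, int, int]] = []
    missing: list[tuple[str, str]] = []

    for p in range(config.n_pops):
        label = labels[p]
        n_genets, n_samples = genets[p], samples_n[p]
        # genet genotypes under within-population HWE
        genet_geno = np.zeros((n_genets, config.n_loci, 2), dtype=np.int64)
        for j in range(config.n_loci):
            draws = rng.choice(
                allele_sizes[j], size=(n_genets, 2), p=pop_freqs[j][p]
            )
            genet_geno[:, j, :] = np.sort(draws, axis=1)
        # each genet gets one ramet, the rest are allocated uniformly
        owner = np.concatenate(
            [
                np.arange(n_genets),
                rng.integers(0, n_genets, size=n_samples - n_genets),
            ]
        )
        rng.shuffle(owner)
        ramet_rank: dict[int, int] = {}
        for i, g in enumerate(owner):
            g = int(g)
            ramet_rank[g] = ramet_rank.get(g, 0) + 1
            sid = f"{label}_c{i + 1:03d}"
            genet_of[sid] = f"{label}_g{g + 1:02d}"
            pop_of[sid] = label
            geno = genet_geno[g].copy()

            if ramet_rank[g] > 1 and rng.random() < config.p_somatic:
                j = int(rng.integers(config.n_loci))
                copy = int(rng.integers(2))
                step = units[j] * (1 if rng.random() < 0.5 else -1)
                old = int(geno[j, copy])
                geno[j, copy] = old + step
                geno[j] = np.sort(geno[j])
                mutations.append((sid, loci[j].locus_id, old, old + step))

            for j in range(config.n_loci):
                if config.p_error > 0 and rng.random() < config.p_error:
                    copy = int(rng.integers(2))
                    old = int(geno[j, copy])
                    new = int(rng.choice(allele_sizes[j]))
                    geno[j, copy] = new
                    geno[j] = np.sort(geno[j])
                    errors.append((sid, loci[j].locus_id, copy, old, new))
                if config.p_missing > 0 and rng.random() < config.p_missing:
                    geno[j] = (MISSING, MISSING)
                    missing.append((sid, loci[j].locus_id))

            samples.append(
                SampleRecord(
                    colony_id=sid,
                    mito_type=label,
                    genotypes={
                        loci[j].locus_id: (int(geno[j, 0]), int(geno[j, 1]))
                        for j in range(config.n_loci)
                    },
                )
            )

    matrix = GenotypeMatrix(loci=loci, samples=samples)
    truth = SimTruth(
        genet_of_sample=genet_of,
        pop_of_sample=pop_of,
        allele_sizes=allele_sizes,
        pop_freqs=pop_freqs,
        ancestral_freqs=anc_freqs,
        mutations=mutations,
        errors=errors,
        missing=missing,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# SSR fixtures
# ---------------------------------------------------------------------------

def _random_flank(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def simulate_repeat_sequences(
    planted: Sequence[tuple[str, int]],
    flank_length: int = 60,
    seed=None,
    max_tries: int = 200,
) -> tuple[list[tuple[str, str]], list[dict]]:
    """One sequence per planted (motif, n_units); flanks free of 3/4-mer runs.

    Returns ``(records, truth)`` where records are (seq_id, sequence)
    pairs and truth rows give the planted repeat's coordinates. Each
    candidate sequence is rejected unless repeat discovery on it returns
    exactly the planted run at the planted coordinates, so flank/junction
    artifacts cannot occur.
    """
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    truth: list[dict] = []
    for idx, (motif, n_units) in enumerate(planted):
        motif = motif.upper()
        if set(motif) - set("ACGT"):
            raise ValueError(f"motif {motif!r} has non-ACGT characters")
        if len(motif) not in (3, 4):
            raise ValueError("motifs must be 3 or 4 bases long")
        seq_id = f"seq{idx + 1:04d}"
        for _ in range(max_tries):
            seq = (
                _random_flank(rng, flank_length)
                + motif * n_units
                + _random_flank(rng, flank_length)
            )
            hits = find_tandem_repeats(seq, seq_id=seq_id)
            if (
                len(hits) == 1
                and hits[0].start == flank_length
                and hits[0].n_units == n_units
                and hits[0].motif == motif
            ):
                break
        else:  # pragma: no cover - rejection loop essentially always succeeds
            raise RuntimeError(f"could not build a clean fixture for {motif!r}")
        records.append((seq_id, seq))
        truth.append(
            {
                "seq_id": seq_id,
                "motif": motif,
                "n_units": n_units,
                "start": flank_length,
                "end": flank_length + len(motif) * n_units,
            }
        )
    return records, truth


def write_fasta(records: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in records:
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
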