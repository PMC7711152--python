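"""Seeded synthetic OTU tables with the structure of a borehole colonization study.

Real deep-aquifer amplicon data of this kind show low diversity (a dominant
OTU holding >15% of most samples), substrate-linked abundance shifts between
colonization surfaces, a transient bloom after an organic-matter pulse with
recovery two incubations later, contaminant OTUs visible in negative
controls, and library sizes spanning roughly 5,000–47,000 reads.  The
generator emulates exactly those features with a Dirichlet-multinomial:
sample compositions are drawn around a fixed rank-abundance baseline whose
mean is perturbed multiplicatively by substrate and incubation effects, then
counts are drawn at a uniformly sampled library size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .otu import SUBSTRATE_BINS, OtuTable, SampleMetadata, ValidationError

DEFAULT_FIXTURE_SEED = 20160511


@dataclass
class SyntheticCommunitySpec:
    """Parameters of the Dirichlet-multinomial community generator.

    ``dominance`` fixes the expected relative abundance of OTU 0; the
    remaining mass decays geometrically (ratio ``decay``) across the other
    OTUs.  ``substrate_effect`` maps an OTU index to a (bin, fold) pair:
    the OTU's expected abundance is multiplied by ``fold`` in samples of that
    bin (then renormalised).  ``perturbation_profile`` does the same per
    incubation number.  ``concentration`` is the Dirichlet precision: larger
    values give tighter biological replicates.
    """

    n_otus: int = 60
    n_samples_per_group: int = 2
    substrate_bins: tuple = ("background", "carbonate", "silica", "mixed", "steel")
    incubations: tuple = (1, 2, 3, 4, 5)
    dominance: float = 0.20
    substrate_effect: dict = field(default_factory=dict)
    perturbation_profile: dict = field(default_factory=dict)
    contaminant_otus: tuple = ()
    library_size_range: tuple = (5000, 47000)
    concentration: float = 100.0
    decay: float = 0.85
    control_depth: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_otus < 1 or self.n_samples_per_group < 1:
            raise ValidationError("n_otus and n_samples_per_group must be ≥ 1")
        if not (0 < self.dominance < 1):
            raise ValidationError("dominance must lie in (0, 1)")
        lo, hi = self.library_size_range
        if lo < 1 or hi < lo:
            raise ValidationError(
                "library_size_range must satisfy 1 ≤ min ≤ max"
            )
        if self.concentration <= 0:
            raise ValidationError("concentration must be positive")
        if not (0 < self.decay < 1):
            raise ValidationError("decay must lie in (0, 1)")
        for b in self.substrate_bins:
            if b not in SUBSTRATE_BINS:
                raise ValidationError(f"unknown substrate bin {b!r}")
        for inc in self.incubations:
            if inc not in range(1, 6):
                raise ValidationError(f"incubation {inc!r} outside 1..5")
        for idx, (b, fold) in self.substrate_effect.items():
            self._check_otu(idx)
            if b not in self.substrate_bins:
                raise ValidationError(f"substrate_effect bin {b!r} not in spec bins")
            if fold <= 0:
                raise ValidationError("fold-changes must be > 0")
        for inc, effects in self.perturbation_profile.items():
            if inc not in self.incubations:
                raise ValidationError(f"perturbation incubation {inc!r} not in spec")
            for idx, fold in effects.items():
                self._check_otu(idx)
                if fold <= 0:
                    raise ValidationError("fold-changes must be > 0")
        for idx in self.contaminant_otus:
            self._check_otu(idx)
        if self.control_depth < 1:
            raise ValidationError("control_depth must be ≥ 1")

    def _check_otu(self, idx: int) -> None:
        if not (0 <= idx < self.n_otus):
            raise ValidationError(
                f"OTU index {idx} outside [0, {self.n_otus})"
            )

    def base_composition(self) -> np.ndarray:
        """Expected composition with no effects: OTU 0 holds ``dominance``."""
        tail = self.decay ** np.arange(self.n_otus - 1)
        tail = (1 - self.dominance) * tail / tail.sum()
        return np.concatenate([[self.dominance], tail])

    def otu_ids(self) -> list[str]:
        width = len(str(self.n_otus - 1))
        return [f"OTU{str(i).zfill(width)}" for i in range(self.n_otus)]


def _mean_for(spec: SyntheticCommunitySpec, bin_label: str, incubation: int) -> np.ndarray:
    mean = spec.base_composition().copy()
    for idx, (b, fold) in spec.substrate_effect.items():
        if b == bin_label:
            mean[idx] *= fold
    for idx, fold in spec.perturbation_profile.get(incubation, {}).items():
        mean[idx] *= fold
    return mean / mean.sum()


def generate_otu_table(
    spec: SyntheticCommunitySpec,
) -> tuple[OtuTable, list[SampleMetadata]]:
    """Draw a full bin × incubation × replicate count table plus metadata."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.library_size_range
    rows, ids, meta = [], [], []
    for inc in spec.incubations:
        for b in spec.substrate_bins:
            mean = _mean_for(spec, b, inc)
            alpha = spec.concentration * mean
            for rep in range(1, spec.n_samples_per_group + 1):
                comp = rng.dirichlet(alpha)
                depth = int(rng.integers(lo, hi + 1))
                counts = rng.multinomial(depth, comp)
                sid = f"{b}_inc{inc}_r{rep}"
                rows.append(counts)
                ids.append(sid)
                meta.append(SampleMetadata(sid, b, incubation=inc))
    counts = pd.DataFrame(
        np.asarray(rows, dtype=np.int64), index=ids, columns=spec.otu_ids()
    )
    return OtuTable(counts), meta


def generate_control_samples(spec: SyntheticCommunitySpec, n_controls: int) -> OtuTable:
    """Low-depth negative controls carrying only the planted contaminants.

    Each contaminant OTU is guaranteed a relative abundance of at least 0.05%
    in every control; all other OTUs are zero (at the default control depth a
    single read already exceeds the contaminant cutoff, so "trace" means
    absent).  Counts always sum to the control depth.
    """
    if n_controls < 1:
        raise ValidationError("n_controls must be ≥ 1")
    rng = np.random.default_rng(spec.seed + 1)
    n = spec.n_otus
    depth = spec.control_depth
    rows, ids = [], []
    contaminants = list(spec.contaminant_otus)
    floor = max(math.ceil(5e-4 * depth), 1)
    for c in range(1, n_controls + 1):
        counts = np.zeros(n, dtype=np.int64)
        if contaminants:
            share = np.full(len(contaminants), 1.0 / len(contaminants))
            comp = rng.dirichlet(spec.concentration * share)
            draw = rng.multinomial(depth, comp)
            counts[contaminants] = draw
            # guarantee the documented floor while preserving the depth
            for k, idx in enumerate(contaminants):
                if counts[idx] < floor:
                    deficit = floor - counts[idx]
                    donor = contaminants[int(np.argmax(counts[contaminants]))]
                    counts[donor] -= deficit
                    counts[idx] += deficit
        ids.append(f"control_{c}")
        rows.append(counts)
    counts = pd.DataFrame(
        np.asarray(rows, dtype=np.int64), index=ids, columns=spec.otu_ids()
    )
    return OtuTable(counts)


def succession_spec(seed: int = DEFAULT_FIXTURE_SEED) -> SyntheticCommunitySpec:
    """Canonical five-incubation study design used by the packaged fixture.

    Three substrate bins carry the system's broad structure (planktonic
    "background" water versus two solid surfaces), each marked by several
    preferentially colonizing OTUs.  Incubation 3 carries the organic-matter
    bloom (two fast-responding heterotroph OTUs), incubation 4 a methanogen
    spike with the bloom decaying, and incubation 5 only a faint residue, so
    the mean composition returns close to the pre-amendment state.  The
    rank-abundance decay is steep (a very low-diversity community) and the
    Dirichlet precision is high, matching duplicate cartridges that cluster
    tightly in ordination; together these keep the two-dimensional embedding
    faithful (stress well below the conventional 0.2 bar).
    """
    return SyntheticCommunitySpec(
        n_otus=60,
        n_samples_per_group=3,
        substrate_bins=("background", "carbonate", "silica"),
        incubations=(1, 2, 3, 4, 5),
        dominance=0.20,
        decay=0.7,
        concentration=2000.0,
        substrate_effect={
            0: ("background", 3.0),   # dominant planktonic OTU, water-enriched
            3: ("background", 4.0),
            6: ("background", 2.5),
            1: ("carbonate", 6.0),
            4: ("carbonate", 3.0),
            7: ("carbonate", 2.0),
            2: ("silica", 6.0),
            5: ("silica", 3.0),
            8: ("silica", 2.0),
        },
        perturbation_profile={
            3: {10: 25.0, 11: 15.0, 12: 2.0},  # heterotroph bloom on organics
            4: {10: 4.0, 11: 3.0, 12: 20.0},   # methanogen phase, bloom decaying
            5: {10: 1.3, 11: 1.2},             # faint residue, near-recovery
        },
        contaminant_otus=(),
        seed=seed,
    )

# OTU indices with designated roles in the succession fixture
BLOOM_OTUS = (10, 11)
METHANOGEN_OTU = 12


def succession_fixture(
    seed: int = DEFAULT_FIXTURE_SEED,
) -> tuple[OtuTable, list[SampleMetadata]]:
    """Deterministically regenerate the packaged succession fixture."""
    return generate_otu_table(succession_spec(seed))


def load_succession_fixture() -> tuple[OtuTable, list[SampleMetadata]]:
    """Load the succession fixture shipped with the package (TSV copies of
    :func:`succession_fixture` at the default seed)."""
    from importlib import resources

    from .io import read_metadata, read_otu_table

    root = resources.files("deepamend") / "data"
    table = read_otu_table(root / "succession_counts.tsv")
    meta = read_metadata(root / "succession_metadata.tsv")
    return table, meta
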