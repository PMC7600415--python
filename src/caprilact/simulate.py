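"""Synthetic dairy-goat herd generator.

Emulates the statistical structure of a Murciano-Granadina milk-recording
data set: 159 goats on 28 farms, a mean (SD) of 3.91 (2.01) lactations per
goat, about 5 monthly controls per lactation with the first control around
21 days after kidding and subsequent controls every 4-6 weeks, lactations
of 210-240 days, and 86 casein-complex haplotypes over 48 SNPs assigned to
animals under Hardy-Weinberg proportions.

Milk yield and component traits follow an Ali–Schaeffer base curve with
i.i.d. Gaussian residual noise per control; somatic cell count follows a
parabolic yield-density curve on the natural scale with multiplicative
lognormal noise (SCC is strictly positive and right-skewed).  Haplotype
effects act additively on the curve-level parameter b0, one contribution
per carried copy.  Lactation number and farm are generated but carried as
metadata only, mirroring a one-way analysis design.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field as _field

import numpy as np

from .curves import ali_schaeffer, parabolic_yield_density
from .errors import ConfigurationError
from .haplotypes import CASEIN_BLOCKS, HaplotypeAssignment, write_haplotypes
from .records import TestDayRecord, write_records

#: Traits simulated from Ali–Schaeffer curves (daily kg / percent).
AS_TRAITS = ("milk_kg", "fat_pct", "protein_pct", "dry_matter_pct", "lactose_pct")
#: Trait simulated from the parabolic yield-density curve (x10^3 cells/mL).
SCC_TRAIT = "scc"

#: Base curve parameter vectors, chosen to give realistic Murciano-Granadina
#: trajectories (milk ~2.2-2.7 kg/day peaking near day 60; components mildly
#: convex over lactation; SCC rising from ~530 to ~870 x10^3 cells/mL).
BASE_CURVE_PARAMS = {
    "milk_kg": (4.532, -2.857, 0.240, -0.958, 0.063),
    "fat_pct": (5.576, -2.082, 3.539, 0.0, 0.0),
    "protein_pct": (3.645, -1.561, 2.654, 0.0, 0.0),
    "dry_matter_pct": (14.689, -3.122, 5.308, 0.0, 0.0),
    "lactose_pct": (4.903, -0.867, 1.475, 0.0, 0.0),
    "scc": (1.9e-3, -6.0e-6, 1.2e-8),
}

#: Residual SDs per control (trait units; for SCC the lognormal sigma).
#: Defaults are generator choices, not values reported by any study.
NOISE_SD = {
    "milk_kg": 0.35,
    "fat_pct": 0.45,
    "protein_pct": 0.25,
    "dry_matter_pct": 0.60,
    "lactose_pct": 0.20,
    "scc": 0.50,
}


@dataclass
class SimConfig:
    """Configuration of one synthetic herd.

    ``haplotype_freqs`` is a list of (label, frequency) pairs summing to 1;
    ``haplotype_seqs`` optionally maps labels to per-block token sequences
    (generated deterministically from the seed when omitted).
    ``effect_sizes`` maps haplotype label -> {trait: additive b0 shift},
    applied once per carried copy.
    """

    n_goats: int = 159
    n_farms: int = 28
    haplotype_freqs: list = None
    haplotype_seqs: dict = None
    effect_sizes: dict = _field(default_factory=dict)
    base_curve_params: dict = _field(
        default_factory=lambda: dict(BASE_CURVE_PARAMS)
    )
    noise_sd: dict = _field(default_factory=lambda: dict(NOISE_SD))
    mean_lactations_per_goat: float = 3.91
    sd_lactations_per_goat: float = 2.01
    controls_per_lactation: int = 5
    first_control_day_mean: float = 21.0
    first_control_day_sd: float = 3.0
    control_interval_range: tuple = (28, 42)
    lactation_length_range: tuple = (210, 240)
    n_haplotypes: int = 86
    seed: int = 0

    def validate(self) -> None:
        if self.n_goats < 1 or self.n_farms < 1 or self.controls_per_lactation < 1:
            raise ConfigurationError("all counts must be >= 1")
        if self.haplotype_freqs is not None:
            if not self.haplotype_freqs:
                raise ConfigurationError("haplotype_freqs must not be empty")
            total = sum(f for _, f in self.haplotype_freqs)
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"haplotype frequencies sum to {total}, expected 1"
                )
        for rng_pair in (self.control_interval_range, self.lactation_length_range):
            if rng_pair[0] > rng_pair[1]:
                raise ConfigurationError(f"range low > high: {rng_pair}")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ConfigurationError("noise_sd must be >= 0")
        missing = [
            t
            for t in AS_TRAITS + (SCC_TRAIT,)
            if t not in self.base_curve_params
        ]
        if missing:
            raise ConfigurationError(f"base_curve_params missing trait(s) {missing}")


@dataclass
class SyntheticDataset:
    """Generated records + haplotype assignments + ground truth."""

    records: list
    assignments: list
    truth: dict

    def write(self, records_path, haplotypes_path) -> None:
        write_records(self.records, records_path)
        write_haplotypes(self.assignments, haplotypes_path)


def default_haplotype_inventory(
    n_haplotypes: int = 86, blocks=CASEIN_BLOCKS, seed: int = 0
):
    """Deterministic inventory of distinct casein-complex haplotypes.

    Each SNP is biallelic; one CSN3 position is an indel site with alleles
    ``.-`` (deletion) and ``AATC`` (insertion).  Haplotype frequencies
    decay smoothly so a few variants are common and many are rare, as in
    real casein haplotype inventories.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    ref, alt = {}, {}
    for b in blocks:
        r = rng.choice(bases, b.n_positions)
        a = np.array([rng.choice([x for x in "ACGT" if x != s]) for s in r])
        ref[b.name], alt[b.name] = r, a
    # indel site: second CSN3 position
    ref["CSN3"] = ref["CSN3"].astype(object)
    alt["CSN3"] = alt["CSN3"].astype(object)
    ref["CSN3"][1], alt["CSN3"][1] = ".-", "AATC"

    seqs: dict[str, dict] = {}
    seen = set()
    idx = 0
    while len(seqs) < n_haplotypes:
        hap = {}
        for b in blocks:
            flip = rng.random(b.n_positions) < 0.30
            hap[b.name] = tuple(
                str(alt[b.name][p]) if flip[p] else str(ref[b.name][p])
                for p in range(b.n_positions)
            )
        key = tuple(hap[b.name] for b in blocks)
        if key in seen:
            continue
        seen.add(key)
        seqs[f"H{idx + 1:03d}"] = hap
        idx += 1
    weights = 1.0 / np.arange(1, n_haplotypes + 1) ** 0.6
    freqs = weights / weights.sum()
    return [(label, float(f)) for label, f in zip(seqs, freqs)], seqs


def assign_diplotypes(freqs, n: int, seed: int):
    """Draw n diplotypes i.i.d. under Hardy-Weinberg proportions."""
    if not freqs:
        raise ConfigurationError("empty haplotype frequency list")
    labels = [l for l, _ in freqs]
    p = np.array([f for _, f in freqs], dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ConfigurationError(f"frequencies sum to {p.sum()}, expected 1")
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(labels), size=(n, 2), p=p)
    return [(labels[i], labels[j]) for i, j in draws]


def _shifted_params(base, shift):
    b = np.asarray(base, dtype=float).copy()
    b[0] += shift
    return b


def simulate_herd(config: SimConfig) -> SyntheticDataset:
    """Generate a synthetic herd; identical seed implies identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.haplotype_seqs is None:
        n_hap = (
            len(config.haplotype_freqs)
            if config.haplotype_freqs is not None
            else config.n_haplotypes
        )
        auto_freqs, auto_seqs = default_haplotype_inventory(n_hap, seed=config.seed)
        if config.haplotype_freqs is None:
            freqs, seqs = auto_freqs, auto_seqs
        else:
            freqs = config.haplotype_freqs
            seqs = {
                label: seq
                for label, seq in zip((l for l, _ in freqs), auto_seqs.values())
            }
    else:
        freqs, seqs = config.haplotype_freqs, config.haplotype_seqs
    diplotypes = assign_diplotypes(
        freqs, config.n_goats, seed=int(rng.integers(2**31))
    )

    lo_i, hi_i = config.control_interval_range
    lo_l, hi_l = config.lactation_length_range
    records = []
    assignments = []
    realized = {}
    base_date = _dt.date(2010, 1, 1)
    for g in range(config.n_goats):
        animal_id = f"G{g + 1:04d}"
        farm_id = f"F{int(rng.integers(config.n_farms)) + 1:02d}"
        h1, h2 = diplotypes[g]
        assignments.append(
            HaplotypeAssignment(animal_id, dict(seqs[h1]), dict(seqs[h2]))
        )
        params = {}
        for trait, base in config.base_curve_params.items():
            shift = sum(
                config.effect_sizes.get(h, {}).get(trait, 0.0) for h in (h1, h2)
            )
            params[trait] = _shifted_params(base, shift)
        realized[animal_id] = {
            "diplotype": (h1, h2),
            "params": {k: v.tolist() for k, v in params.items()},
        }
        n_lact = max(
            1,
            int(
                round(
                    rng.normal(
                        config.mean_lactations_per_goat,
                        config.sd_lactations_per_goat,
                    )
                )
            ),
        )
        kidding = base_date + _dt.timedelta(days=int(rng.integers(0, 2000)))
        for lact_no in range(1, n_lact + 1):
            length = int(rng.integers(lo_l, hi_l + 1))
            d = max(5, int(round(rng.normal(
                config.first_control_day_mean, config.first_control_day_sd
            ))))
            dims = []
            while len(dims) < config.controls_per_lactation and d <= length:
                dims.append(d)
                d += int(rng.integers(lo_i, hi_i + 1))
            values = {}
            for trait in AS_TRAITS:
                if trait not in params:
                    continue
                mean = ali_schaeffer(np.array(dims, float), params[trait])
                values[trait] = mean + rng.normal(
                    0.0, config.noise_sd.get(trait, 0.0), len(dims)
                )
            if SCC_TRAIT in params:
                mean = parabolic_yield_density(
                    np.array(dims, float), params[SCC_TRAIT]
                )
                values[SCC_TRAIT] = mean * np.exp(
                    rng.normal(0.0, config.noise_sd.get(SCC_TRAIT, 0.0), len(dims))
                )
            for i, dim in enumerate(dims):
                records.append(
                    TestDayRecord(
                        animal_id=animal_id,
                        farm_id=farm_id,
                        lactation_no=lact_no,
                        kidding_date=kidding,
                        control_date=kidding + _dt.timedelta(days=int(dim)),
                        milk_kg=float(values["milk_kg"][i]),
                        fat_pct=float(values["fat_pct"][i]),
                        protein_pct=float(values["protein_pct"][i]),
                        dry_matter_pct=float(values["dry_matter_pct"][i]),
                        lactose_pct=float(values["lactose_pct"][i]),
                        scc=float(values["scc"][i]),
                    )
                )
            kidding = kidding + _dt.timedelta(days=int(rng.integers(300, 400)))
    truth = {
        "config": config,
        "haplotype_freqs": freqs,
        "animals": realized,
    }
    return SyntheticDataset(records=records, assignments=assignments, truth=truth)
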