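"""Synthetic fragment-level chromatin datasets with known ground truth.

The generator plants transcription-factor motif sites of three
accessibility classes on a random genome and emits the fragment files
the downstream analyses consume:

* MNase dyads: each site carries a motif-covering nucleosome component
  (weight = occupancy over the motif) plus a phased array of
  nucleosomes at +/- k * spacing with Gaussian positional jitter; a
  remodeler-depleted ("kd") condition rescales the flanking-array
  amplitude (more alleles with a productively bound factor -> stronger
  phasing) and the motif occupancy.
* Accessibility (transposition) fragments: uniform genomic background
  plus class- and condition-dependent extra rate within +/-200 bp of
  each site.
* ChIP fragments: centers normal around bound motifs with per-site
  weight proportional to occupancy, plus uniform background — including
  the weak occupancy regime that models motif sampling outside peaks.

Every emitted file draws from its own RNG stream derived from
``(seed, file tag)``, so regenerating one assay never perturbs another.
"""
from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fragments import FragmentRecord
from .intervals import GenomicInterval
from .motifs import IUPAC_CODES, reverse_complement, scan_motif

__all__ = [
    "CLASSES",
    "SimConfig",
    "GenomeSim",
    "generate_genome",
    "simulate_mnase_fragments",
    "simulate_accessibility_fragments",
    "simulate_chip_fragments",
    "write_bedpe",
    "write_fasta",
    "write_dataset",
]

CLASSES = (
    "newly_accessible",
    "constitutively_accessible",
    "constitutively_inaccessible",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _default_occupancy() -> dict:
    # motif-covering nucleosome weight per class x MNase condition;
    # kd lowers motif occupancy at closed sites (dyads move off the motif)
    return {
        "newly_accessible": {"control": 0.2, "kd": 0.1},
        "constitutively_accessible": {"control": 0.3, "kd": 0.3},
        "constitutively_inaccessible": {"control": 0.5, "kd": 0.25},
    }


def _default_accessibility() -> dict:
    # extra transposition events/bp within +/-200 bp, per class x condition
    return {
        "newly_accessible": {"pre": 0.0, "post": 0.15},
        "constitutively_accessible": {"pre": 0.15, "post": 0.15},
        "constitutively_inaccessible": {"pre": 0.0, "post": 0.0},
    }


@dataclass
class SimConfig:
    """Generative parameters of the synthetic study.

    The simulated chromosome stands for a captured window of a larger
    genome: ``background_rate`` (fragments/bp) corresponds to a full
    library of ``library_size`` fragments, which is the denominator the
    classifier's depth normalization should use.
    """

    genome_length: int = 5_000_000
    chrom: str = "chrS"
    n_sites_per_class: int = 300
    motif: str = "WGATAR"
    nucleosome_spacing: int = 190
    dyad_jitter_sd: float = 20.0
    n_phased_nucleosomes: int = 3
    occupancy_over_motif: dict = field(default_factory=_default_occupancy)
    eviction_shift: dict = field(default_factory=lambda: {"control": 1.0, "kd": 1.5})
    accessibility_rate: dict = field(default_factory=_default_accessibility)
    background_rate: float = 0.005
    library_size: int = 15_000_000
    scale_target: int = 10_000_000
    mnase_depth: int = 100_000
    mnase_background_fraction: float = 0.3
    chip_depth: int = 100_000
    chip_background_fraction: float = 0.5
    chip_fragment_sd: float = 60.0
    chip_occupancy: dict = field(
        default_factory=lambda: {c: 0.5 for c in CLASSES}
    )
    nucleosomal_fragment_length: tuple = (150.0, 12.0, 100, 200)
    chip_fragment_length: tuple = (200.0, 40.0, 100, 300)
    accessibility_fragment_length: tuple = (60, 120)
    seed: int = 0

    def validate(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.n_sites_per_class < 0:
            raise ValueError("n_sites_per_class must be >= 0")
        if self.nucleosome_spacing <= 147:
            raise ValueError("nucleosome_spacing must exceed 147 bp")
        if self.dyad_jitter_sd < 0:
            raise ValueError("dyad_jitter_sd must be >= 0")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if not (0.0 <= self.mnase_background_fraction <= 1.0):
            raise ValueError("mnase_background_fraction must be in [0, 1]")
        if not (0.0 <= self.chip_background_fraction <= 1.0):
            raise ValueError("chip_background_fraction must be in [0, 1]")
        for cls in CLASSES:
            for cond, v in self.occupancy_over_motif[cls].items():
                if not (0.0 <= v <= 1.0):
                    raise ValueError(
                        f"occupancy_over_motif[{cls}][{cond}] must be in [0, 1]"
                    )
            for cond, v in self.accessibility_rate[cls].items():
                if v < 0:
                    raise ValueError(
                        f"accessibility_rate[{cls}][{cond}] must be >= 0"
                    )

    def rng(self, tag: str) -> np.random.Generator:
        """One independent stream per emitted file: (seed, crc32(tag))."""
        return np.random.default_rng([self.seed, zlib.crc32(tag.encode()) & 0x7FFFFFFF])

    def scale_factor(self) -> float:
        """Depth-normalization factor implied by the declared library."""
        return self.scale_target / self.library_size

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GenomeSim:
    """A generated genome with its planted sites and ground truth."""

    config: SimConfig
    sequence: str
    sites: list[GenomicInterval]
    truth: pd.DataFrame


def _truncnorm_lengths(rng, n, params) -> np.ndarray:
    mean, sd, lo, hi = params
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return np.rint(
        stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    ).astype(np.int64)


def generate_genome(config: SimConfig) -> GenomeSim:
    """Generate a uniform random genome with planted motif sites.

    Spurious background occurrences of the motif (either strand) are
    rewritten by single-base substitutions so that a consensus scan of
    the emitted sequence returns exactly the planted sites; planting is
    on a random strand per site. Sites are placed with a minimum
    separation of twice the phased-array span so neighbouring arrays
    never interleave.
    """
    config.validate()
    rng = config.rng("genome")
    L = config.genome_length
    n_sites = config.n_sites_per_class * len(CLASSES)
    motif = config.motif.upper()
    mlen = len(motif)

    margin = config.n_phased_nucleosomes * config.nucleosome_spacing + 1000
    min_gap = 2 * config.n_phased_nucleosomes * config.nucleosome_spacing
    slack = L - 2 * margin - (max(n_sites - 1, 0)) * min_gap
    if n_sites > 0 and slack <= 0:
        raise ValueError(
            f"cannot place {n_sites} sites with gap {min_gap} on a "
            f"{L} bp genome (infeasible packing)"
        )

    seq = rng.integers(0, 4, size=L, dtype=np.uint8)  # base codes 0..3

    if n_sites > 0:
        offsets = np.sort(rng.uniform(0, slack, size=n_sites))
        centers = (margin + offsets + np.arange(n_sites) * min_gap).astype(np.int64)
    else:
        centers = np.array([], dtype=np.int64)
    labels = np.repeat(CLASSES, config.n_sites_per_class)
    rng.shuffle(labels)
    strands = rng.choice(np.array(["+", "-"]), size=n_sites)

    base_to_code = {b: i for i, b in enumerate("ACGT")}
    protected = np.zeros(L, dtype=bool)
    motif_spans = []
    for center, strand in zip(centers, strands):
        realized = "".join(
            IUPAC_CODES[c][rng.integers(0, len(IUPAC_CODES[c]))] for c in motif
        )
        genomic = realized if strand == "+" else reverse_complement(realized)
        start = int(center) - mlen // 2
        seq[start : start + mlen] = [base_to_code[b] for b in genomic]
        protected[start : start + mlen] = True
        motif_spans.append((start, start + mlen))
    planted = set(motif_spans)

    # scrub spurious matches so the scan oracle returns exactly the plant
    rc_motif = None
    for _ in range(40):
        text = _BASES[seq].tobytes().decode()
        hits = scan_motif(text, motif, both_strands=True, chrom=config.chrom)
        spurious = [h for h in hits if (h.start, h.end) not in planted]
        if not spurious:
            break
        from .motifs import reverse_complement_pattern

        rc_motif = rc_motif or reverse_complement_pattern(motif)
        for h in spurious:
            for o in range(mlen):
                p = h.start + o
                if protected[p]:
                    continue
                allowed = set(IUPAC_CODES[motif[o]]) | set(IUPAC_CODES[rc_motif[o]])
                choices = [b for b in "ACGT" if b not in allowed]
                if not choices:
                    continue
                seq[p] = base_to_code[choices[int(rng.integers(0, len(choices)))]]
                break
    else:
        raise RuntimeError("motif scrubbing did not converge")

    sequence = _BASES[seq].tobytes().decode()

    sites = [
        GenomicInterval(
            config.chrom,
            int(c) - 100,
            int(c) + 100,
            name=f"site_{i}|{label}",
            strand=str(strand),
        )
        for i, (c, label, strand) in enumerate(zip(centers, labels, strands))
    ]
    truth = pd.DataFrame(
        {
            "site_id": [f"site_{i}" for i in range(n_sites)],
            "chrom": config.chrom,
            "center": centers,
            "start": centers - 100,
            "end": centers + 100,
            "label": labels,
            "strand": strands,
            "motif_start": [s for s, _ in motif_spans],
            "motif_end": [e for _, e in motif_spans],
            "occupancy_control": [
                config.occupancy_over_motif[l]["control"] for l in labels
            ],
            "occupancy_kd": [config.occupancy_over_motif[l]["kd"] for l in labels],
            "accessibility_pre": [
                config.accessibility_rate[l]["pre"] for l in labels
            ],
            "accessibility_post": [
                config.accessibility_rate[l]["post"] for l in labels
            ],
        }
    )
    return GenomeSim(config, sequence, sites, truth)


def theoretical_dyad_centers(center: int, config: SimConfig) -> np.ndarray:
    """Motif-central plus phased flanking dyad positions for one site."""
    ks = np.arange(1, config.n_phased_nucleosomes + 1)
    return np.sort(
        np.concatenate(
            [[center], center + ks * config.nucleosome_spacing,
             center - ks * config.nucleosome_spacing]
        )
    )


def _fragments_from_dyads(rng, chrom, dyad_pos, lengths, genome_length):
    starts = dyad_pos - lengths // 2
    starts = np.clip(starts, 0, np.maximum(genome_length - lengths, 0))
    ends = starts + lengths
    return [
        FragmentRecord(chrom, int(s), int(e)) for s, e in zip(starts, ends)
    ]


def simulate_mnase_fragments(
    truth: pd.DataFrame, condition: str, config: SimConfig
) -> list[FragmentRecord]:
    """Mono-nucleosome-scale fragments whose midpoints are dyads.

    Per site the dyad mixture is: motif-covering component with weight
    ``occupancy_over_motif(class, condition)`` and flanking components
    at ``+/- k * spacing`` (k = 1..n, uniform over k) whose total
    weight is ``eviction_shift(condition)``; jitter is Gaussian. A
    fraction of the total depth is uniform background (omitted entirely
    when ``background_rate`` is zero).
    """
    if condition not in ("control", "kd"):
        raise ValueError("condition must be 'control' or 'kd'")
    rng = config.rng(f"mnase_{condition}")
    depth = config.mnase_depth
    n_bg = (
        int(round(depth * config.mnase_background_fraction))
        if config.background_rate > 0
        else 0
    )
    n_site = depth - n_bg if len(truth) else 0
    if len(truth) == 0:
        n_bg = n_bg  # background only (or nothing when rate is zero)

    dyad_positions = []
    if n_site > 0:
        centers = truth["center"].to_numpy(dtype=np.int64)
        occ = np.array(
            [config.occupancy_over_motif[l][condition] for l in truth["label"]]
        )
        shift = float(config.eviction_shift[condition])
        weights = occ + shift
        if weights.sum() > 0:
            site_idx = rng.choice(len(truth), size=n_site, p=weights / weights.sum())
            p_central = np.divide(
                occ[site_idx],
                weights[site_idx],
                out=np.zeros(n_site),
                where=weights[site_idx] > 0,
            )
            central = rng.random(n_site) < p_central
            k = rng.integers(1, config.n_phased_nucleosomes + 1, size=n_site)
            sign = rng.choice(np.array([-1, 1]), size=n_site)
            offset = np.where(central, 0, sign * k * config.nucleosome_spacing)
            jitter = (
                rng.normal(0.0, config.dyad_jitter_sd, size=n_site)
                if config.dyad_jitter_sd > 0
                else np.zeros(n_site)
            )
            dyad_positions.append(
                np.rint(centers[site_idx] + offset + jitter).astype(np.int64)
            )
    if n_bg > 0:
        dyad_positions.append(
            rng.integers(0, config.genome_length, size=n_bg, dtype=np.int64)
        )
    if not dyad_positions:
        return []
    dyad_pos = np.clip(
        np.concatenate(dyad_positions), 0, config.genome_length - 1
    )
    lengths = _truncnorm_lengths(
        rng, dyad_pos.size, config.nucleosomal_fragment_length
    )
    return _fragments_from_dyads(
        rng, config.chrom, dyad_pos, lengths, config.genome_length
    )


def simulate_accessibility_fragments(
    truth: pd.DataFrame, condition: str, config: SimConfig
) -> list[FragmentRecord]:
    """Short transposition fragments: Poisson background genome-wide plus
    class/condition-dependent extra rate within +/-200 bp of each site."""
    if condition not in ("pre", "post"):
        raise ValueError("condition must be 'pre' or 'post'")
    rng = config.rng(f"atac_{condition}")
    L = config.genome_length
    positions = []
    n_bg = rng.poisson(config.background_rate * L)
    if n_bg > 0:
        positions.append(rng.integers(0, L, size=n_bg, dtype=np.int64))
    if len(truth):
        centers = truth["center"].to_numpy(dtype=np.int64)
        rates = np.array(
            [config.accessibility_rate[l][condition] for l in truth["label"]]
        )
        counts = rng.poisson(rates * 400)
        total = int(counts.sum())
        if total > 0:
            site_centers = np.repeat(centers, counts)
            offsets = rng.integers(-200, 200, size=total, dtype=np.int64)
            positions.append(np.clip(site_centers + offsets, 0, L - 1))
    if not positions:
        return []
    pos = np.concatenate(positions)
    lo, hi = config.accessibility_fragment_length
    lengths = rng.integers(lo, hi + 1, size=pos.size, dtype=np.int64)
    return _fragments_from_dyads(rng, config.chrom, pos, lengths, L)


def simulate_chip_fragments(
    truth: pd.DataFrame,
    occupancy_map: Mapping[str, float] | Sequence[float] | None = None,
    config: SimConfig | None = None,
) -> list[FragmentRecord]:
    """ChIP fragments: centers normal (sd ``chip_fragment_sd``) around
    motifs with per-site weight proportional to occupancy, plus uniform
    background. ``occupancy_map`` is either a per-class mapping or a
    per-site weight sequence; zero occupancy everywhere yields pure
    background."""
    if config is None:
        raise ValueError("config is required")
    rng = config.rng("chip")
    depth = config.chip_depth
    if occupancy_map is None:
        occupancy_map = config.chip_occupancy
    if isinstance(occupancy_map, Mapping):
        occ = np.array([occupancy_map[l] for l in truth["label"]], dtype=float)
    else:
        occ = np.asarray(occupancy_map, dtype=float)
        if occ.shape != (len(truth),):
            raise ValueError("per-site occupancy length mismatch")
    total_occ = occ.sum() if len(truth) else 0.0
    if total_occ > 0:
        n_bg = int(round(depth * config.chip_background_fraction))
        n_site = depth - n_bg
    else:
        n_bg, n_site = depth, 0
    positions = []
    if n_site > 0:
        centers = truth["center"].to_numpy(dtype=np.int64)
        site_idx = rng.choice(len(truth), size=n_site, p=occ / total_occ)
        positions.append(
            np.rint(
                centers[site_idx]
                + rng.normal(0.0, config.chip_fragment_sd, size=n_site)
            ).astype(np.int64)
        )
    if n_bg > 0:
        positions.append(
            rng.integers(0, config.genome_length, size=n_bg, dtype=np.int64)
        )
    if not positions:
        return []
    pos = np.clip(np.concatenate(positions), 0, config.genome_length - 1)
    lengths = _truncnorm_lengths(rng, pos.size, config.chip_fragment_length)
    return _fragments_from_dyads(
        rng, config.chrom, pos, lengths, config.genome_length
    )


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def write_bedpe(
    fragments: Sequence[FragmentRecord], path, read_length: int = 50
) -> None:
    """Emit fragments as 10-column BEDPE mate pairs splitting each
    fragment (mates anchored at the two fragment ends)."""
    with open(path, "w") as fh:
        for i, frag in enumerate(fragments):
            e1 = min(frag.start + read_length, frag.end)
            s2 = max(frag.end - read_length, frag.start)
            fh.write(
                f"{frag.chrom}\t{frag.start}\t{e1}"
                f"\t{frag.chrom}\t{s2}\t{frag.end}"
                f"\tfrag{i}\t.\t+\t-\n"
            )


def write_fasta(sequence: str, chrom: str, path, width: int = 70) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    record = SeqRecord(Seq(sequence), id=chrom, description="synthetic genome")
    with open(path, "w") as fh:
        SeqIO.write([record], fh, "fasta")


def write_dataset(config: SimConfig, outdir) -> dict:
    """Generate and write a full synthetic dataset.

    Emits genome FASTA, chrom.sizes, planted-site BED, ground-truth
    TSV, a config echo (JSON), BEDPE per assay x condition, and a
    manifest with sha256 checksums of every file. Returns the manifest.
    """
    import hashlib

    from . import __version__
    from .intervals import write_bed, write_chrom_sizes

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = generate_genome(config)

    files: dict[str, Path] = {}

    files["genome.fa"] = outdir / "genome.fa"
    write_fasta(sim.sequence, config.chrom, files["genome.fa"])
    files["chrom.sizes"] = outdir / "chrom.sizes"
    write_chrom_sizes({config.chrom: config.genome_length}, files["chrom.sizes"])
    files["sites.bed"] = outdir / "sites.bed"
    write_bed(sim.sites, files["sites.bed"])
    files["truth.tsv"] = outdir / "truth.tsv"
    sim.truth.to_csv(files["truth.tsv"], sep="\t", index=False)
    files["config.json"] = outdir / "config.json"
    with open(files["config.json"], "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")

    for condition in ("control", "kd"):
        name = f"mnase_{condition}.bedpe"
        files[name] = outdir / name
        write_bedpe(
            simulate_mnase_fragments(sim.truth, condition, config), files[name]
        )
    for condition in ("pre", "post"):
        name = f"atac_{condition}.bedpe"
        files[name] = outdir / name
        write_bedpe(
            simulate_accessibility_fragments(sim.truth, condition, config),
            files[name],
        )
    files["chip.bedpe"] = outdir / "chip.bedpe"
    write_bedpe(
        simulate_chip_fragments(sim.truth, None, config), files["chip.bedpe"]
    )

    config_blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    manifest = {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(config_blob).hexdigest(),
        "seed": config.seed,
        "files": {
            name: hashlib.sha256(path.read_bytes()).hexdigest()
            for name, path in sorted(files.items())
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
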