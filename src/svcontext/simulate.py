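"""Synthetic genome, annotation, and SV-callset simulator.

Generates a toy multi-chromosome reference whose structural-variant classes
carry the mechanistic determinants the models are meant to learn:

* TE insertions occur immediately after an endonuclease target motif
  (default ``TAAAA``) planted so the motif occupies positions -1..+3
  relative to the breakpoint — the L1-endonuclease cleavage geometry.
* Deletions carry breakpoint-spanning microhomology: an identical k-mer
  ends at the left breakpoint and begins at the right breakpoint, so the
  flank-joined context window contains a tandem homologous pair across
  the junction.
* Inversions cluster around a small number of hotspot centres.
* Simple-repeat SVs fall inside planted tandem-repeat intervals.

Small-variant density is elevated near breakpoints, per-gene constraint
scores decrease with local SV density, and allele frequencies are
stochastically higher at determinant-driven sites.  Every planted
determinant is recorded in a ground-truth manifest and is recoverable from
the emitted files alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .dataset import (AnnotationBundle, BreakpointIndex, ConservationTrack,
                      IntervalSet, PointSet, SVRecord)
from .errors import ConfigurationError, PlacementError
from . import io as svio

SV_CLASSES = ("te_insertion", "deletion_mh", "simple_repeat", "inversion")

_DEFAULT_COUNTS = {"te_insertion": 250, "deletion_mh": 250,
                   "simple_repeat": 125, "inversion": 125}


@dataclass
class SimulationConfig:
    n_chromosomes: int = 3
    chrom_length: int = 200_000
    gc_by_chrom: Optional[list[float]] = None
    n_sv_per_class: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_COUNTS))
    te_target_motif: str = "TAAAA"
    mh_length_distribution: dict[int, float] = field(default_factory=lambda: {8: 1.0})
    hotspot_count: int = 3
    hotspot_sd: float = 2000.0
    snp_rate_background: float = 0.001
    snp_rate_near_bp: float = 0.01
    indel_rate_scale: float = 0.1
    breakpoint_halo: int = 200
    conservation_halo: int = 100
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (500, 1500)
    constraint_intercept: float = 1.0
    constraint_slope: float = 0.15
    constraint_noise_sd: float = 0.3
    af_beta_background: tuple[float, float] = (0.2, 2.0)
    af_beta_determinant: tuple[float, float] = (1.0, 2.0)
    edge_margin: int = 300
    seed: int = 42

    def __post_init__(self):
        if self.gc_by_chrom is None:
            base = [0.40, 0.45, 0.50]
            self.gc_by_chrom = [base[i % 3] for i in range(self.n_chromosomes)]
        if len(self.gc_by_chrom) != self.n_chromosomes:
            raise ConfigurationError("gc_by_chrom must have one entry per chromosome")
        if not all(0.0 < g < 1.0 for g in self.gc_by_chrom):
            raise ConfigurationError("GC fractions must lie in (0, 1)")
        for r in (self.snp_rate_background, self.snp_rate_near_bp):
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError("rates must lie in [0, 1]")
        if any(v < 0 for v in self.n_sv_per_class.values()):
            raise ConfigurationError("class counts must be >= 0")
        unknown = set(self.n_sv_per_class) - set(SV_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown SV classes {sorted(unknown)}")
        if self.chrom_length < 4000:
            raise ConfigurationError("chrom_length too small (need >= 10 windows)")
        if abs(sum(self.mh_length_distribution.values()) - 1.0) > 1e-9:
            raise ConfigurationError("mh_length_distribution must sum to 1")


@dataclass
class GroundTruthManifest:
    """Per-SV planted determinants plus hotspot and gene ground truth."""

    svs: list[dict] = field(default_factory=list)
    hotspots: list[dict] = field(default_factory=list)
    genes: list[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"svs": self.svs, "hotspots": self.hotspots, "genes": self.genes},
            indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruthManifest":
        d = json.loads(Path(path).read_text())
        return cls(svs=d["svs"], hotspots=d["hotspots"], genes=d["genes"])


class Reference:
    """Mutable in-memory reference; chromosome slices return plain strings."""

    class _Chrom:
        __slots__ = ("buf",)

        def __init__(self, buf: bytearray):
            self.buf = buf

        def __len__(self):
            return len(self.buf)

        def __getitem__(self, key):
            return self.buf[key].decode()

        def __str__(self):
            return self.buf.decode()

    def __init__(self, sequences: Mapping[str, str]):
        self._chroms = {name: self._Chrom(bytearray(seq, "ascii"))
                        for name, seq in sequences.items()}

    def keys(self):
        return self._chroms.keys()

    def __contains__(self, chrom):
        return chrom in self._chroms

    def __getitem__(self, chrom):
        return self._chroms[chrom]

    def plant(self, chrom: str, pos: int, motif: str) -> None:
        self._chroms[chrom].buf[pos:pos + len(motif)] = motif.encode("ascii")

    def sequences(self) -> dict[str, str]:
        return {name: str(c) for name, c in self._chroms.items()}


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2]
    return "".join(np.array(list("ATCG"))[rng.choice(4, size=n, p=probs)])


def _place_nonoverlapping(rng, occupied: list[tuple[int, int]], length: int,
                          lo: int, hi: int, tries: int = 200) -> int:
    """Uniform start in [lo, hi) avoiding occupied intervals (with margin)."""
    if hi - lo <= length:
        raise PlacementError("chromosome too short for requested element")
    for _ in range(tries):
        s = int(rng.integers(lo, hi - length))
        e = s + length
        if all(e + 5 <= a or b + 5 <= s for a, b in occupied):
            occupied.append((s, e))
            return s
    raise PlacementError("could not place element after bounded retries")


# ---------------------------------------------------------------------------
# Reference + annotations
# ---------------------------------------------------------------------------

def generate_reference(config: SimulationConfig):
    """Generate chromosomes and planted repeat/TE annotation intervals.

    Returns ``(reference, annotations)`` where annotations maps
    ``simple_repeat`` / ``alu`` / ``l1`` to interval sets.  Planted element
    sequences are drawn from each chromosome's base composition, so the
    empirical GC stays within +/-0.02 of the target.
    """
    rng = np.random.default_rng(config.seed)
    seqs: dict[str, str] = {}
    ann = {key: {} for key in ("simple_repeat", "alu", "l1")}
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        gc = config.gc_by_chrom[ci]
        L = config.chrom_length
        seq = bytearray(_random_seq(rng, L, gc), "ascii")
        occupied: list[tuple[int, int]] = []
        lo, hi = config.edge_margin, L - config.edge_margin

        def plant(element: str) -> tuple[int, int]:
            s = _place_nonoverlapping(rng, occupied, len(element), lo, hi)
            seq[s:s + len(element)] = element.encode("ascii")
            return s, s + len(element)

        # tandem simple repeats: short unit repeated to 80-160 bp
        reps = []
        for _ in range(max(L // 6000, 1)):
            unit = _random_seq(rng, int(rng.integers(2, 6)), gc)
            total = int(rng.integers(80, 161))
            element = (unit * (total // len(unit) + 1))[:total]
            reps.append(plant(element))
        ann["simple_repeat"][chrom] = reps

        # Alu-like family: one consensus per chromosome, mutated copies
        alu_consensus = _random_seq(rng, 300, gc)
        alus = []
        for _ in range(max(L // 12000, 1)):
            copy = _mutate(rng, alu_consensus, 0.05, gc)
            n = int(rng.integers(280, 301))
            alus.append(plant(copy[:n]))
        ann["alu"][chrom] = alus

        # L1-like family: longer consensus, 5'-truncated copies
        l1_consensus = _random_seq(rng, 800, gc)
        l1s = []
        for _ in range(max(L // 20000, 1)):
            copy = _mutate(rng, l1_consensus, 0.05, gc)
            n = int(rng.integers(400, 801))
            l1s.append(plant(copy[-n:]))
        ann["l1"][chrom] = l1s

        seqs[chrom] = seq.decode()
        measured_gc = (seqs[chrom].count("G") + seqs[chrom].count("C")) / L
        if abs(measured_gc - gc) > 0.02:
            raise PlacementError(
                f"{chrom}: GC {measured_gc:.3f} strayed past +/-0.02 of {gc}")
    annotations = {key: IntervalSet(chroms) for key, chroms in ann.items()}
    return Reference(seqs), annotations


def _mutate(rng, seq: str, rate: float, gc: float) -> str:
    arr = np.array(list(seq))
    hits = rng.random(len(arr)) < rate
    if hits.any():
        arr[hits] = np.array(list(_random_seq(rng, int(hits.sum()), gc)))
    return "".join(arr)


# ---------------------------------------------------------------------------
# Structural variants
# ---------------------------------------------------------------------------

def simulate_svs(reference: Reference, annotations: Mapping[str, IntervalSet],
                 config: SimulationConfig):
    """Plant SVs of each class with their mechanistic determinants.

    Returns ``(records, manifest)``.  Planting writes motif/microhomology
    sequence into the reference, so call before extracting any windows.
    """
    rng = np.random.default_rng(config.seed + 1)
    chroms = sorted(reference.keys())
    clens = {c: len(reference[c]) for c in chroms}
    weights = np.array([clens[c] for c in chroms], float)
    weights /= weights.sum()
    max_k = max(config.mh_length_distribution) if config.mh_length_distribution else 0
    margin = config.edge_margin + max_k + len(config.te_target_motif)
    used_bp: set[tuple[str, int]] = set()
    footprints: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    records: list[SVRecord] = []
    manifest = GroundTruthManifest()

    def gc_of(chrom):
        return config.gc_by_chrom[chroms.index(chrom)]

    def claim(chrom, positions, spans) -> bool:
        if any((chrom, p) in used_bp for p in positions):
            return False
        occ = footprints[chrom]
        if any(not (e <= a or b <= s) for s, e in spans for a, b in occ):
            return False
        for p in positions:
            used_bp.add((chrom, p))
        occ.extend(spans)
        return True

    def rand_chrom():
        return chroms[rng.choice(len(chroms), p=weights)]

    counts = {**{c: 0 for c in SV_CLASSES}, **{}}
    n_per = {c: config.n_sv_per_class.get(c, 0) for c in SV_CLASSES}

    # --- TE insertions: motif at -1..+3 relative to the breakpoint -------
    motif = config.te_target_motif.upper()
    for i in range(n_per["te_insertion"]):
        for _ in range(300):
            chrom = rand_chrom()
            p = int(rng.integers(margin, clens[chrom] - margin))
            if claim(chrom, [p], [(p - 1, p - 1 + len(motif))]):
                break
        else:
            raise PlacementError("insufficient space for TE insertions")
        reference.plant(chrom, p - 1, motif)
        length = int(rng.integers(250, 351))
        rc = rng.choice(["SINE/Alu", "LINE/L1", "Retroposon/SVA"],
                        p=[0.7, 0.15, 0.15])
        rec = SVRecord(chrom=chrom, start=p, end=p, svtype="INS", length=length,
                       id=f"te_{i}", repeat_class=str(rc))
        records.append(rec)
        manifest.svs.append({"id": rec.id, "class": "te_insertion",
                             "chrom": chrom, "start": p, "end": p,
                             "determinant": {"kind": "te_motif", "motif": motif,
                                             "motif_start": p - 1}})

    # --- deletions with breakpoint-spanning microhomology -----------------
    mh_lengths = sorted(config.mh_length_distribution)
    mh_probs = [config.mh_length_distribution[k] for k in mh_lengths]
    for i in range(n_per["deletion_mh"]):
        for _ in range(300):
            chrom = rand_chrom()
            k = int(rng.choice(mh_lengths, p=mh_probs))
            length = int(rng.integers(100, 1001))
            start = int(rng.integers(margin, clens[chrom] - margin - length))
            end = start + length
            if claim(chrom, [start, end], [(start - k, start), (end, end + k)]):
                break
        else:
            raise PlacementError("insufficient space for deletions")
        m = _random_seq(rng, k, gc_of(chrom))
        reference.plant(chrom, start - k, m)
        reference.plant(chrom, end, m)
        rec = SVRecord(chrom=chrom, start=start, end=end, svtype="DEL",
                       length=length, id=f"del_{i}")
        records.append(rec)
        manifest.svs.append({"id": rec.id, "class": "deletion_mh",
                             "chrom": chrom, "start": start, "end": end,
                             "determinant": {"kind": "microhomology",
                                             "mh_seq": m, "length": k}})

    # --- simple-repeat SVs: deletions inside planted repeat tracts --------
    repeat_ivs = annotations["simple_repeat"]
    all_reps = [(c, s, e) for c in chroms for s, e in repeat_ivs.intervals(c)]
    if n_per["simple_repeat"] and not all_reps:
        raise PlacementError("no planted simple repeats to host simple_repeat SVs")
    for i in range(n_per["simple_repeat"]):
        for _ in range(300):
            chrom, rs, re_ = all_reps[int(rng.integers(len(all_reps)))]
            iv_len = re_ - rs
            length = int(rng.integers(50, iv_len + 1)) if iv_len > 50 else iv_len
            start = int(rng.integers(rs, re_ - length + 1))
            end = start + length
            if claim(chrom, [start, end], [(start, start + 1), (end, end + 1)]):
                break
        else:
            raise PlacementError("insufficient space for simple-repeat SVs")
        rec = SVRecord(chrom=chrom, start=start, end=end, svtype="DEL",
                       length=length, id=f"sr_{i}", repeat_class="simple_repeat")
        records.append(rec)
        manifest.svs.append({"id": rec.id, "class": "simple_repeat",
                             "chrom": chrom, "start": start, "end": end,
                             "determinant": {"kind": "repeat_overlap",
                                             "interval": [rs, re_]}})

    # --- inversions: breakpoints from hotspot-centred normals -------------
    if n_per["inversion"]:
        for h in range(config.hotspot_count):
            chrom = rand_chrom()
            center = int(rng.integers(margin + 10_000, clens[chrom] - margin - 10_000))
            manifest.hotspots.append({"id": h, "chrom": chrom, "center": center})
        for i in range(n_per["inversion"]):
            for _ in range(500):
                hs = manifest.hotspots[int(rng.integers(len(manifest.hotspots)))]
                chrom = hs["chrom"]
                bp1 = int(round(rng.normal(hs["center"], config.hotspot_sd)))
                length = int(rng.integers(200, 2001))
                bp2 = bp1 + length
                if bp1 < margin or bp2 > clens[chrom] - margin:
                    continue
                if claim(chrom, [bp1, bp2], [(bp1, bp1 + 1), (bp2, bp2 + 1)]):
                    break
            else:
                raise PlacementError("insufficient space for inversions")
            rec = SVRecord(chrom=chrom, start=bp1, end=bp2, svtype="INV",
                           length=length, id=f"inv_{i}")
            records.append(rec)
            manifest.svs.append({"id": rec.id, "class": "inversion",
                                 "chrom": chrom, "start": bp1, "end": bp2,
                                 "determinant": {"kind": "hotspot",
                                                 "hotspot_id": hs["id"],
                                                 "center": hs["center"]}})
    return records, manifest


# ---------------------------------------------------------------------------
# Small variants
# ---------------------------------------------------------------------------

def simulate_small_variants(reference: Reference, sv_records, config: SimulationConfig):
    """Per-bp Bernoulli SNP/indel positions with elevated density inside
    the breakpoint halo.  Returns ``{"snp"|"small_ins"|"small_del": {chrom:
    sorted positions}}``."""
    rng = np.random.default_rng(config.seed + 2)
    halo = config.breakpoint_halo
    out = {"snp": {}, "small_ins": {}, "small_del": {}}
    for chrom in sorted(reference.keys()):
        L = len(reference[chrom])
        rate = np.full(L, config.snp_rate_background)
        for rec in sv_records:
            if rec.chrom != chrom:
                continue
            for bp in rec.breakpoints:
                rate[max(bp - halo, 0):min(bp + halo, L)] = config.snp_rate_near_bp
        for kind, scale in (("snp", 1.0), ("small_ins", config.indel_rate_scale),
                            ("small_del", config.indel_rate_scale)):
            hits = np.nonzero(rng.random(L) < rate * scale)[0]
            out[kind][chrom] = np.unique(hits)
    return out


# ---------------------------------------------------------------------------
# Genes, constraint, allele frequency
# ---------------------------------------------------------------------------

def simulate_genes_and_constraint(reference: Reference, sv_records,
                                  config: SimulationConfig, manifest=None):
    """Non-overlapping genes with constraint anti-correlated with local SV
    density, plus per-SV allele frequencies (higher at determinant sites).

    Returns ``(genes, exons, gene_table)``; allele frequencies are written
    onto the records in place.
    """
    rng = np.random.default_rng(config.seed + 3)
    chroms = sorted(reference.keys())
    clens = {c: len(reference[c]) for c in chroms}
    occupied = {c: [] for c in chroms}
    genes, exons = {c: [] for c in chroms}, {c: [] for c in chroms}
    rows = []
    lo_len, hi_len = config.gene_length_range
    for gi in range(config.n_genes):
        chrom = chroms[gi % len(chroms)]
        length = int(rng.integers(lo_len, hi_len + 1))
        s = _place_nonoverlapping(rng, occupied[chrom], length,
                                  config.edge_margin,
                                  clens[chrom] - config.edge_margin)
        e = s + length
        genes[chrom].append((s, e))
        for _ in range(3):
            ex_len = min(150, length // 4)
            ex_s = int(rng.integers(s, e - ex_len))
            exons[chrom].append((ex_s, ex_s + ex_len))
        count = sum(1 for r in sv_records if r.chrom == chrom
                    and any(s - 200 <= bp < e + 200 for bp in r.breakpoints))
        score = (config.constraint_intercept - config.constraint_slope * count
                 + (rng.normal(0.0, config.constraint_noise_sd)
                    if config.constraint_noise_sd > 0 else 0.0))
        rows.append({"gene_id": f"gene_{gi}", "chrom": chrom, "start": s,
                     "end": e, "constraint_score": score, "n_sv": count})
        if manifest is not None:
            manifest.genes.append({"gene_id": f"gene_{gi}", "chrom": chrom,
                                   "start": s, "end": e,
                                   "constraint_score": score,
                                   "expected_sv_count": count})
    determinant_classes = {"te_insertion", "deletion_mh"}
    class_by_id = {}
    if manifest is not None:
        class_by_id = {sv["id"]: sv["class"] for sv in manifest.svs}
    a0, b0 = config.af_beta_background
    a1, b1 = config.af_beta_determinant
    for rec in sv_records:
        if class_by_id.get(rec.id) in determinant_classes:
            rec.allele_frequency = float(rng.beta(a1, b1))
        else:
            rec.allele_frequency = float(rng.beta(a0, b0))
    return IntervalSet(genes), IntervalSet(exons), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# End-to-end + serialization
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    config: SimulationConfig
    reference: Reference
    annotations: dict[str, IntervalSet]
    records: list[SVRecord]
    small_variants: dict[str, dict[str, np.ndarray]]
    genes: IntervalSet
    exons: IntervalSet
    gene_table: pd.DataFrame
    manifest: GroundTruthManifest

    def annotation_bundle(self) -> AnnotationBundle:
        """Assemble the feature-computation view of this simulation."""
        track = breakpoint_conservation_track(self.reference, self.records,
                                              self.config.conservation_halo)
        intervals = dict(self.annotations)
        intervals["gene"] = self.genes
        intervals["exon"] = self.exons
        return AnnotationBundle(
            intervals=intervals,
            points={k: PointSet(v) for k, v in self.small_variants.items()},
            sv_breakpoints=BreakpointIndex(self.records),
            conservation=track)


def simulate_fixture(config: SimulationConfig) -> SimulationResult:
    """Run the whole simulator in memory."""
    reference, annotations = generate_reference(config)
    records, manifest = simulate_svs(reference, annotations, config)
    small = simulate_small_variants(reference, records, config)
    genes, exons, gene_table = simulate_genes_and_constraint(
        reference, records, config, manifest)
    return SimulationResult(config, reference, annotations, records, small,
                            genes, exons, gene_table, manifest)


def breakpoint_conservation_track(reference: Reference, records,
                                  halo: int = 100) -> ConservationTrack:
    """Baseline 1.0 with -1.0 halos of +/-halo bp around every breakpoint."""
    segs = {}
    for chrom in sorted(reference.keys()):
        L = len(reference[chrom])
        halos = []
        for rec in records:
            if rec.chrom != chrom:
                continue
            for bp in rec.breakpoints:
                halos.append((max(bp - halo, 0), min(bp + halo, L)))
        halos.sort()
        merged = []
        for s, e in halos:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
            else:
                merged.append((s, e))
        out, cursor = [], 0
        for s, e in merged:
            if s > cursor:
                out.append((cursor, s, 1.0))
            out.append((s, e, -1.0))
            cursor = e
        if cursor < L:
            out.append((cursor, L, 1.0))
        segs[chrom] = out
    return ConservationTrack(segs)


def write_fixture(output_dir, result: SimulationResult) -> dict[str, Path]:
    """Serialize everything to standard text formats; returns the path map."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    contigs = {c: len(result.reference[c]) for c in sorted(result.reference.keys())}
    paths = {
        "fasta": out / "reference.fa",
        "sv_vcf": out / "svs.vcf",
        "small_vcf": out / "small_variants.vcf",
        "conservation": out / "conservation.bedGraph",
        "gene_scores": out / "gene_scores.tsv",
        "genes_bed": out / "genes.bed",
        "manifest": out / "manifest.json",
        "config": out / "config.json",
    }
    svio.write_fasta(paths["fasta"], result.reference.sequences())
    svio.write_sv_vcf(paths["sv_vcf"], result.records, contigs, result.reference)
    svio.write_small_variant_vcf(
        paths["small_vcf"], result.small_variants["snp"],
        result.small_variants["small_ins"], result.small_variants["small_del"],
        result.reference, contigs)
    for key in ("simple_repeat", "alu", "l1"):
        paths[f"{key}_bed"] = out / f"{key}.bed"
        svio.write_bed(paths[f"{key}_bed"], result.annotations[key], key)
    paths["exon_bed"] = out / "exons.bed"
    svio.write_bed(paths["exon_bed"], result.exons, "exon")
    svio.write_bed(paths["genes_bed"], result.genes, "gene")
    svio.write_bedgraph(paths["conservation"],
                        breakpoint_conservation_track(
                            result.reference, result.records,
                            result.config.conservation_halo))
    svio.write_gene_scores(paths["gene_scores"], result.gene_table)
    result.manifest.to_json(paths["manifest"])
    cfg = asdict(result.config)
    cfg["mh_length_distribution"] = {str(k): v for k, v in
                                     cfg["mh_length_distribution"].items()}
    Path(paths["config"]).write_text(json.dumps(cfg, indent=1))
    return paths


def load_fixture(fixture_dir):
    """Re-assemble records and the annotation bundle from emitted files."""
    d = Path(fixture_dir)
    reference = svio.read_fasta(d / "reference.fa")
    records = svio.read_sv_vcf(d / "svs.vcf")
    points = svio.read_small_variant_vcf(d / "small_variants.vcf")
    intervals = {}
    for key, fname in (("simple_repeat", "simple_repeat.bed"), ("alu", "alu.bed"),
                       ("l1", "l1.bed"), ("exon", "exons.bed"), ("gene", "genes.bed")):
        if (d / fname).exists():
            intervals[key] = svio.read_bed(d / fname)
    bundle = AnnotationBundle(
        intervals=intervals, points=points,
        sv_breakpoints=BreakpointIndex(records),
        conservation=svio.read_bedgraph(d / "conservation.bedGraph"))
    gene_table = svio.read_gene_scores(d / "gene_scores.tsv")
    manifest = GroundTruthManifest.from_json(d / "manifest.json")
    return reference, records, bundle, gene_table, manifest
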