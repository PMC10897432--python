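"""Toy-genome simulator with planted regulatory architecture.

Generates a small multi-chromosome genome whose annotation, strand-specific
5' read-start tracks, raw count matrix, differential tables and ACR peaks
contain known planted instances of every feature class the pipeline detects:

* protein-coding genes, each with one planted TSS peak;
* antisense non-coding TSSs inside gene bodies (proximal and distal, the
  distal ones sometimes within the 200 bp post-TTS extension);
* divergent promoters (ncTSS-pcTSS, head-to-head within 500 bp) with a
  planted, distance-decaying expression correlation;
* head-to-head pcTSS-pcTSS gene pairs with independent expression;
* bidirectional non-coding promoters (ncTSS-ncTSS pairs, correlated);
* intergenic unidirectional ncTSSs (half with a reconstructable transcript);
* convergent nc decoy pairs that must never be reported as bidirectional;
* enhancers (from nc-nc pairs and unidirectional ncTSSs) linked to a nearby
  protein-coding gene with a planted activity-expression correlation;
* exosome-sensitive features upregulated in the two mutant samples;
* ACRs over every promoter and enhancer, inside gene bodies, over
  transposable elements, and as intergenic decoys.

Read starts around each planted summit follow a two-sided geometric decay
(sharp summits with an adjustable 80%-width); per-sample totals follow a
negative-binomial around a stage-profile mean over a six-time-point course,
with two exosome-mutant samples reusing the seedling (L57) stage.  Planted
correlations use a shared latent profile plus independent noise, with
rejection resampling (up to 10 draws) because correlation estimates at
n = 6 samples are noisy.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .core_model import (
    AcrPeak,
    AnalysisParameters,
    BedInterval,
    ExpressionMatrix,
    GeneModel,
    GenomeAnnotation,
    SignalTrack,
    TranscriptCandidate,
    TranscriptModel,
    TssPeak,
    write_bed,
    write_bedgraph_pair,
    write_de_table,
    write_matrix,
)

__all__ = ["SimulationConfig", "TruthTables", "SimulationResult",
           "simulate", "emit_fixture", "PRESETS"]

_PAD = 600          # clear bp kept on each side of a unit's features
_UNIT_GAP = 500     # clear bp between consecutive units
_L57_INDEX = 4      # mutants are sampled at the L57 (seedling) stage


@dataclass
class SimulationConfig:
    """Planted-feature counts and statistical knobs of the simulator.

    Defaults define the "mini" study genome: 3 x 500 kb chromosomes and 150
    protein-coding genes hosting 30 proximal + 30 distal antisense TSSs,
    40 divergent promoters, 20 bidirectional non-coding promoters, 20
    enhancer-gene links planted at r ~ 0.8, plus decoys.
    """

    seed: int
    n_chromosomes: int = 3
    chrom_length: int = 500_000
    n_genes: int = 150
    n_antisense_proximal: int = 30
    n_antisense_distal: int = 30
    n_divergent: int = 40
    n_divergent_wide: int = 0
    n_pc_pc: int = 10
    n_bidirectional_nc: int = 20
    n_unidirectional_intergenic: int = 20
    n_convergent_decoys: int = 10
    n_enhancer_linked_genes: int = 20
    n_exosome_sensitive: int = 30
    n_annotated_lncrna: int = 10
    n_small_rna: int = 5
    n_te: int = 6
    n_acr_decoys: int = 20
    timepoints: tuple = ("DS", "S24", "S72", "L26", "L57", "L168")
    mutants: tuple = ("hen2_4", "rrp4_2")
    summit_dispersion: float = 0.75      # geometric decay p of read-start offsets
    noise_rate: float = 2.0              # background read starts / kb / strand / sample
    corr_planted: float = 0.8
    anticorr_planted: float = -0.6
    expression_dispersion: float = 0.1   # NB dispersion phi (var = mu + phi mu^2)
    amplitude_log_mean: float = 6.0      # lognormal mean read-start amplitude
    amplitude_log_sd: float = 0.8
    antisense_amplitude_ratio: float = 8.0   # median sense:antisense amplitude
    corr_tol: float = 0.15
    resample_max: int = 10

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        n_hosts = (
            2 * self.n_pc_pc
            + self.n_antisense_proximal
            + self.n_antisense_distal
            + self.n_divergent
            + self.n_divergent_wide
            + self.n_enhancer_linked_genes
        )
        if self.n_genes < n_hosts:
            raise ValueError(
                f"n_genes={self.n_genes} cannot host {n_hosts} feature-bearing genes"
            )
        if self.n_enhancer_linked_genes > (
            self.n_bidirectional_nc + self.n_unidirectional_intergenic
        ):
            raise ValueError("more enhancer links requested than enhancer sources")

    @property
    def samples(self) -> list[str]:
        return list(self.timepoints) + list(self.mutants)

    def to_yaml(self, path: str) -> None:
        data = asdict(self)
        data["timepoints"] = list(self.timepoints)
        data["mutants"] = list(self.mutants)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "seed" not in data:
            raise ValueError(f"{path}: seed is mandatory in a simulation config")
        for key in ("timepoints", "mutants"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


PRESETS: dict[str, dict] = {
    "mini": {},  # the defaults ARE the mini study genome
    "micro": {
        "n_chromosomes": 2,
        "chrom_length": 150_000,
        "n_genes": 30,
        "n_antisense_proximal": 5,
        "n_antisense_distal": 5,
        "n_divergent": 8,
        "n_pc_pc": 2,
        "n_bidirectional_nc": 4,
        "n_unidirectional_intergenic": 4,
        "n_convergent_decoys": 2,
        "n_enhancer_linked_genes": 4,
        "n_exosome_sensitive": 8,
        "n_annotated_lncrna": 2,
        "n_small_rna": 2,
        "n_te": 2,
        "n_acr_decoys": 4,
    },
}


@dataclass
class TruthTables:
    """Planted ground truth, one table per feature class."""

    peaks: pd.DataFrame           # peak_id, role, truth_category, host_gene
    pairs: pd.DataFrame           # kind, minus_peak, plus_peak, distance, planted_r
    antisense: pd.DataFrame       # gene, sense/antisense peaks, class, planted_r
    enhancer_links: pd.DataFrame  # source peaks, linked gene, planted_r
    enhancer_sources: pd.DataFrame  # every expected enhancer-candidate source
    exosome: pd.DataFrame         # assay, mutant, feature, lfc, q, truth_call
    acrs: pd.DataFrame            # acr_id, truth_label


@dataclass
class SimulationResult:
    config: SimulationConfig
    annotation: GenomeAnnotation
    peaks: list[TssPeak]
    tracks: dict[str, SignalTrack]       # sample -> per-strand 5' read starts
    counts: pd.DataFrame                 # peak x sample raw read-start counts
    de_tables: dict[str, pd.DataFrame]   # "{assay}_{mutant}" -> DE table
    acrs: list[AcrPeak]
    te_intervals: list[BedInterval]
    transcripts: list[TranscriptCandidate]
    truth: TruthTables

    @property
    def pooled_track(self) -> SignalTrack:
        return SignalTrack.pooled(self.tracks.values())


# ---------------------------------------------------------------------------
# Internal feature bookkeeping
# ---------------------------------------------------------------------------


class _Feature:
    """A planted TSS: genomic placement plus expression-generation state."""

    __slots__ = ("fid", "chrom", "summit", "strand", "peak_start", "peak_end",
                 "role", "truth_category", "host_gene", "partner",
                 "mean_tc", "counts_tc", "planted_r", "_gen")

    def __init__(self, fid, chrom, summit, strand, peak_start, peak_end, role,
                 truth_category, host_gene=None, partner=None):
        self.fid = fid
        self.chrom = chrom
        self.summit = summit
        self.strand = strand
        self.peak_start = peak_start
        self.peak_end = peak_end
        self.role = role
        self.truth_category = truth_category
        self.host_gene = host_gene
        self.partner = partner
        self.mean_tc = None
        self.counts_tc = None
        self.planted_r = None


def _stage_profiles(n_stages: int = 6, width: float = 0.9) -> np.ndarray:
    t = np.arange(n_stages, dtype=float)
    return np.array(
        [np.exp(-0.5 * ((t - k) / width) ** 2) for k in range(n_stages)]
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + phi mu^2."""
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-9)
    if phi <= 0:
        return rng.poisson(mu)
    r = 1.0 / phi
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


class _ExpressionPlanner:
    """Draws per-feature time-course means/counts, with correlation planting."""

    def __init__(self, rng: np.random.Generator, cfg: SimulationConfig) -> None:
        self.rng = rng
        self.cfg = cfg
        self.profiles = _stage_profiles(len(cfg.timepoints))

    def _amplitude(self, scale: float = 1.0) -> float:
        cfg = self.cfg
        return scale * float(
            np.exp(self.rng.normal(cfg.amplitude_log_mean, cfg.amplitude_log_sd))
        )

    def independent(self, feat: _Feature, scale: float = 1.0) -> None:
        """A feature on its own randomly chosen stage profile; the amplitude
        is the mean expression level (profiles are mean-normalized)."""
        amp = self._amplitude(scale)
        k = int(self.rng.integers(len(self.profiles)))
        shape = 0.05 + self.profiles[k]
        mean = amp * shape / shape.mean()
        feat.mean_tc = mean
        feat.counts_tc = _nb_draw(self.rng, mean, self.cfg.expression_dispersion)

    def correlated(self, feat: _Feature, base_counts: np.ndarray,
                   target_r: float, scale: float = 1.0) -> None:
        """Plant a partner whose counts correlate with ``base_counts`` at
        approximately ``target_r`` (rejection-resampled, best of <=10)."""
        cfg = self.cfg
        amp = self._amplitude(scale)
        u = np.log1p(np.asarray(base_counts, float))
        if u.std() == 0:
            self.independent(feat, scale)
            feat.planted_r = target_r
            return
        u = (u - u.mean()) / u.std()
        best = None
        for _ in range(cfg.resample_max):
            eps = self.rng.normal(size=u.size)
            z = target_r * u + np.sqrt(max(0.0, 1 - target_r ** 2)) * eps
            shape = np.exp(0.7 * z)
            mean = amp * shape / shape.mean()
            counts = _nb_draw(self.rng, mean, cfg.expression_dispersion)
            r = _pearson(counts, base_counts)
            err = abs((r if np.isfinite(r) else 0.0) - target_r)
            if best is None or err < best[0]:
                best = (err, mean, counts, r)
            if err <= cfg.corr_tol:
                break
        _, feat.mean_tc, feat.counts_tc, realized = best
        feat.planted_r = target_r


# ---------------------------------------------------------------------------
# Genome layout: placement units
# ---------------------------------------------------------------------------


class _Unit:
    """Features in local coordinates; placed on a chromosome later."""

    def __init__(self, span: int) -> None:
        self.span = span
        self.genes: list[dict] = []       # local start/end/strand/biotype/id
        self.features: list[dict] = []    # local TSS descriptions
        self.acrs: list[dict] = []
        self.tes: list[dict] = []
        self.transcripts: list[dict] = []

    def flip(self) -> None:
        """Mirror the unit so layouts occur in both orientations."""
        s = self.span

        def _iv(d):
            d["start"], d["end"] = s - d["end"], s - d["start"]

        for g in self.genes:
            _iv(g)
            g["strand"] = "-" if g["strand"] == "+" else "+"
        for f in self.features:
            f["summit"] = s - 1 - f["summit"]
            f["peak_start"], f["peak_end"] = (
                s - f["peak_end"], s - f["peak_start"]
            )
            f["strand"] = "-" if f["strand"] == "+" else "+"
        for a in self.acrs:
            _iv(a)
            a["summit"] = s - 1 - a["summit"]
        for t in self.tes:
            _iv(t)
        for tx in self.transcripts:
            _iv(tx)
            tx["strand"] = "-" if tx["strand"] == "+" else "+"


class _Builder:
    def __init__(self, rng: np.random.Generator, cfg: SimulationConfig) -> None:
        self.rng = rng
        self.cfg = cfg
        self.units: list[_Unit] = []
        self._gene_n = 0
        self._peak_n = 0
        self._acr_n = 0
        self._te_n = 0
        self._tx_n = 0

    # -- id factories -----------------------------------------------------

    def _gid(self) -> str:
        self._gene_n += 1
        return f"g{self._gene_n:04d}"

    def _pid(self) -> str:
        self._peak_n += 1
        return f"tss{self._peak_n:04d}"

    def _aid(self) -> str:
        self._acr_n += 1
        return f"acr{self._acr_n:04d}"

    def _teid(self) -> str:
        self._te_n += 1
        return f"te{self._te_n:02d}"

    def _txid(self) -> str:
        self._tx_n += 1
        return f"tx{self._tx_n:04d}"

    # -- shared pieces ----------------------------------------------------

    def _peak_iv(self, summit: int) -> tuple[int, int]:
        w = int(self.rng.integers(120, 201))
        return summit - w // 2, summit - w // 2 + w

    def _add_gene(self, unit: _Unit, start: int, end: int, strand: str,
                  biotype: str = "protein_coding") -> str:
        gid = self._gid()
        unit.genes.append(
            dict(id=gid, start=start, end=end, strand=strand, biotype=biotype)
        )
        return gid

    def _add_tss(self, unit: _Unit, summit: int, strand: str, role: str,
                 category: str, host=None, partner=None,
                 amp_scale: float = 1.0, corr_to=None, target_r=None) -> str:
        fid = self._pid()
        ps, pe = self._peak_iv(summit)
        unit.features.append(
            dict(id=fid, summit=summit, strand=strand, peak_start=ps,
                 peak_end=pe, role=role, category=category, host=host,
                 partner=partner, amp_scale=amp_scale, corr_to=corr_to,
                 target_r=target_r)
        )
        return fid

    def _add_promoter_acr(self, unit: _Unit, tss: int, strand: str) -> None:
        # summit 150 bp upstream of the TSS in transcription orientation:
        # safely inside the (-400, +100) promoter window
        if strand == "+":
            summit, start, end = tss - 150, tss - 500, tss + 201
        else:
            summit, start, end = tss + 150, tss - 200, tss + 501
        unit.acrs.append(
            dict(id=self._aid(), start=start, end=end, summit=summit,
                 label="Promoter")
        )

    # -- units ------------------------------------------------------------

    def plain_gene(self, with_intragenic_acr: bool) -> _Unit:
        L = int(self.rng.integers(1500, 4001))
        u = _Unit(L + 2 * _PAD)
        gid = self._add_gene(u, _PAD, _PAD + L, "+")
        self._add_tss(u, _PAD, "+", "pc", "mRNA", host=gid)
        self._add_promoter_acr(u, _PAD, "+")
        if with_intragenic_acr:
            c = _PAD + L // 2
            u.acrs.append(
                dict(id=self._aid(), start=c - 200, end=c + 200, summit=c,
                     label="Intragenic")
            )
        return u

    def pcpc_pair(self) -> _Unit:
        L1 = int(self.rng.integers(1500, 3001))
        L2 = int(self.rng.integers(1500, 3001))
        d = int(self.rng.integers(80, 481))
        u = _Unit(L1 + d + 1 + L2 + 2 * _PAD)
        tss1 = _PAD + L1 - 1                   # minus-strand gene, TSS at right
        tss2 = tss1 + d                        # plus-strand gene, TSS at left
        g1 = self._add_gene(u, _PAD, _PAD + L1, "-")
        g2 = self._add_gene(u, tss2, tss2 + L2, "+")
        a = self._add_tss(u, tss1, "-", "pcpc", "mRNA", host=g1)
        b = self._add_tss(u, tss2, "+", "pcpc", "mRNA", host=g2,
                          partner=a, corr_to=a, target_r=None)
        u.features[-2]["partner"] = b
        self._add_promoter_acr(u, tss1, "-")
        self._add_promoter_acr(u, tss2, "+")
        u.pair = dict(kind="pcTSS-pcTSS", minus=a, plus=b, distance=d,
                      planted_r=None)
        return u

    def antisense_host(self, proximal: bool) -> _Unit:
        L = int(self.rng.integers(3000, 5001))
        u = _Unit(L + 2 * _PAD)
        gid = self._add_gene(u, _PAD, _PAD + L, "+")
        sense = self._add_tss(u, _PAD, "+", "pc", "mRNA", host=gid)
        if proximal:
            # first half of the body and well >1 kb from the TTS
            offset = int(self.rng.integers(int(0.10 * L), int(0.35 * L)))
        else:
            # near (or just past) the TTS: 200 bp extension exercised
            tts_dist = int(self.rng.integers(-150, 801))
            offset = L - 1 - tts_dist
        summit = _PAD + offset
        role = "antisense_proximal" if proximal else "antisense_distal"
        # planted correlation drawn from a mixture of regimes
        regime = int(self.rng.integers(3))
        target = (self.cfg.corr_planted, self.cfg.anticorr_planted, None)[regime]
        anti = self._add_tss(
            u, summit, "-", role, "unstable", host=gid, partner=sense,
            amp_scale=1.0 / self.cfg.antisense_amplitude_ratio,
            corr_to=sense, target_r=target,
        )
        u.features[-2]["partner"] = anti
        self._add_promoter_acr(u, _PAD, "+")
        u.antisense = dict(
            gene=gid, sense=sense, antisense=anti,
            truth_class="proximal" if proximal else "distal",
            offset=offset, gene_length=L,
        )
        return u

    def divergent(self, wide: bool) -> _Unit:
        L = int(self.rng.integers(1500, 4001))
        d = int(self.rng.integers(550, 1451)) if wide else int(
            self.rng.integers(80, 481)
        )
        u = _Unit(_PAD + d + L + 2 * _PAD)
        m = _PAD                               # nc TSS, minus strand, faces left
        p = m + d                              # gene TSS, plus strand
        gid = self._add_gene(u, p, p + L, "+")
        target = self.cfg.corr_planted * float(np.exp(-(d - 80) / 600.0))
        pc = self._add_tss(u, p, "+", "pc", "mRNA", host=gid)
        nc = self._add_tss(
            u, m, "-", "divergent_wide_nc" if wide else "divergent_nc",
            "unstable", partner=pc, amp_scale=0.4, corr_to=pc, target_r=target,
        )
        u.features[-2]["partner"] = nc
        self._add_promoter_acr(u, p, "+")
        u.pair = dict(
            kind="ncTSS-pcTSS-wide" if wide else "ncTSS-pcTSS",
            minus=nc, plus=pc, distance=d, planted_r=target,
        )
        return u

    def ncnc_pair(self, linked: bool) -> _Unit:
        d = int(self.rng.integers(80, 481))
        span = 2 * _PAD + d
        gene = None
        if linked:
            L = int(self.rng.integers(1500, 3001))
            g = int(self.rng.integers(1200, 3001))
            gene = dict(gap=g, length=L)
            span = _PAD + d + g + L + _PAD
        u = _Unit(span)
        m = _PAD
        p = m + d
        a = self._add_tss(u, m, "-", "ncnc", "unstable", amp_scale=0.5)
        b = self._add_tss(u, p, "+", "ncnc", "unstable", partner=a,
                          amp_scale=0.5, corr_to=a,
                          target_r=self.cfg.corr_planted)
        u.features[-2]["partner"] = b
        u.pair = dict(kind="ncTSS-ncTSS", minus=a, plus=b, distance=d,
                      planted_r=self.cfg.corr_planted)
        # enhancer ACR over the pair midpoint; the midpoint sits inside the
        # members' own (-400,+100) promoter windows, so the ladder labels it
        # Promoter
        mid = (m + p) // 2
        u.acrs.append(
            dict(id=self._aid(), start=mid - 200, end=mid + 200, summit=mid,
                 label="Promoter")
        )
        if linked:
            tss = p + gene["gap"]
            gid = self._add_gene(u, tss, tss + gene["length"], "+")
            pc = self._add_tss(u, tss, "+", "pc", "mRNA", host=gid,
                               corr_to=(a, b), target_r=self.cfg.corr_planted)
            self._add_promoter_acr(u, tss, "+")
            u.enhancer_link = dict(sources=(a, b), gene=gid, gene_peak=pc,
                                   planted_r=self.cfg.corr_planted)
        return u

    def unidirectional(self, linked: bool, with_transcript: bool) -> _Unit:
        s = _PAD
        tlen = int(self.rng.integers(300, 801)) if with_transcript else 0
        extent = s + 10 + tlen  # rightward transcript reach
        gene = None
        if linked:
            L = int(self.rng.integers(1500, 3001))
            g = int(self.rng.integers(1200, 3501))
            gene = dict(gap=g, length=L)
            extent = max(extent, s + g + L)
        u = _Unit(extent + _PAD)
        category = "putativeLncRNA" if with_transcript else "unstable"
        nc = self._add_tss(u, s, "+", "unidirectional", category,
                           amp_scale=0.5)
        # ACR on the nc TSS: inside its own promoter window -> Promoter
        u.acrs.append(
            dict(id=self._aid(), start=s - 200, end=s + 200, summit=s,
                 label="Promoter")
        )
        if with_transcript:
            # plus-strand transcript: 5' end 10 bp from the summit
            u.transcripts.append(
                dict(id=self._txid(), start=s + 10, end=s + 10 + tlen,
                     strand="+")
            )
        if linked:
            tss = s + gene["gap"]
            gid = self._add_gene(u, tss, tss + gene["length"], "+")
            pc = self._add_tss(u, tss, "+", "pc", "mRNA", host=gid,
                               corr_to=(nc,), target_r=self.cfg.corr_planted)
            self._add_promoter_acr(u, tss, "+")
            u.enhancer_link = dict(sources=(nc,), gene=gid, gene_peak=pc,
                                   planted_r=self.cfg.corr_planted)
        return u

    def convergent_decoy(self) -> _Unit:
        d = int(self.rng.integers(100, 401))
        u = _Unit(2 * _PAD + d)
        # plus TSS on the left, minus TSS on the right: facing each other
        a = self._add_tss(u, _PAD, "+", "convergent", "unstable",
                          amp_scale=0.5)
        b = self._add_tss(u, _PAD + d, "-", "convergent", "unstable",
                          partner=a, amp_scale=0.5)
        u.features[-2]["partner"] = b
        u.pair = dict(kind="convergent", minus=b, plus=a, distance=d,
                      planted_r=None)
        return u

    def annotated_nc_gene(self, biotype: str, short: bool) -> _Unit:
        L = int(self.rng.integers(200, 401)) if short else int(
            self.rng.integers(800, 2001)
        )
        u = _Unit(L + 2 * _PAD)
        gid = self._add_gene(u, _PAD, _PAD + L, "+", biotype=biotype)
        category = "otherNcRNA" if short else "lncRNA"
        self._add_tss(u, _PAD, "+", "annotated_nc", category, host=gid,
                      amp_scale=0.5)
        self._add_promoter_acr(u, _PAD, "+")
        return u

    def te_unit(self) -> _Unit:
        L = int(self.rng.integers(600, 1201))
        u = _Unit(L + 2 * _PAD)
        u.tes.append(dict(id=self._teid(), start=_PAD, end=_PAD + L))
        c = _PAD + L // 2
        u.acrs.append(
            dict(id=self._aid(), start=c - 150, end=c + 150, summit=c,
                 label="TE")
        )
        return u

    def acr_decoy(self) -> _Unit:
        u = _Unit(2 * _PAD)
        u.acrs.append(
            dict(id=self._aid(), start=_PAD - 150, end=_PAD + 150,
                 summit=_PAD, label="Intergenic")
        )
        return u


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------


def _build_units(rng: np.random.Generator, cfg: SimulationConfig) -> list[_Unit]:
    b = _Builder(rng, cfg)
    units: list[_Unit] = []

    n_linked_ncnc = min(cfg.n_enhancer_linked_genes, cfg.n_bidirectional_nc)
    n_linked_uni = cfg.n_enhancer_linked_genes - n_linked_ncnc
    # split links roughly evenly across the two source classes
    half = cfg.n_enhancer_linked_genes // 2
    if cfg.n_bidirectional_nc >= half and cfg.n_unidirectional_intergenic >= (
        cfg.n_enhancer_linked_genes - half
    ):
        n_linked_ncnc = half
        n_linked_uni = cfg.n_enhancer_linked_genes - half

    for _ in range(cfg.n_pc_pc):
        units.append(b.pcpc_pair())
    for _ in range(cfg.n_antisense_proximal):
        units.append(b.antisense_host(proximal=True))
    for _ in range(cfg.n_antisense_distal):
        units.append(b.antisense_host(proximal=False))
    for _ in range(cfg.n_divergent):
        units.append(b.divergent(wide=False))
    for _ in range(cfg.n_divergent_wide):
        units.append(b.divergent(wide=True))
    for i in range(cfg.n_bidirectional_nc):
        units.append(b.ncnc_pair(linked=i < n_linked_ncnc))
    for i in range(cfg.n_unidirectional_intergenic):
        units.append(b.unidirectional(linked=i < n_linked_uni,
                                      with_transcript=i % 2 == 0))
    for _ in range(cfg.n_convergent_decoys):
        units.append(b.convergent_decoy())

    n_plain = cfg.n_genes - b._gene_n
    for i in range(n_plain):
        units.append(b.plain_gene(with_intragenic_acr=True))

    lnc_biotypes = ["long_noncoding_rna", "antisense_long_non_coding_rna",
                    "novel_transcribed_region", "other_rna", "pseudogene"]
    for i in range(cfg.n_annotated_lncrna):
        units.append(
            b.annotated_nc_gene(lnc_biotypes[i % len(lnc_biotypes)], short=False)
        )
    small_biotypes = ["miRNA", "small_nuclear_rna", "small_nucleolar_rna",
                      "pre_trna"]
    for i in range(cfg.n_small_rna):
        units.append(
            b.annotated_nc_gene(small_biotypes[i % len(small_biotypes)],
                                short=True)
        )
    for _ in range(cfg.n_te):
        units.append(b.te_unit())
    for _ in range(cfg.n_acr_decoys):
        units.append(b.acr_decoy())

    for u in units:
        if rng.random() < 0.5:
            u.flip()
    return [units[i] for i in rng.permutation(len(units))]


def _place_units(units: list[_Unit], cfg: SimulationConfig) -> list[tuple]:
    """Assign each unit a (chrom, offset); error before output if infeasible."""
    total_needed = sum(u.span + _UNIT_GAP for u in units) + 2000 * cfg.n_chromosomes
    capacity = cfg.n_chromosomes * cfg.chrom_length
    if total_needed > capacity:
        raise ValueError(
            f"infeasible packing: planted features need ~{total_needed} bp "
            f"but the genome holds {capacity} bp"
        )
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    cursors = {c: 1000 for c in chroms}
    placed = []
    for u in units:
        chrom = min(chroms, key=lambda c: cursors[c])
        if cursors[chrom] + u.span + 1000 > cfg.chrom_length:
            raise ValueError("infeasible packing: chromosome overflow")
        placed.append((u, chrom, cursors[chrom]))
        cursors[chrom] += u.span + _UNIT_GAP
    return placed


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run the simulator; deterministic given ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    units = _build_units(rng, cfg)
    placed = _place_units(units, cfg)

    chrom_lengths = {f"chr{i + 1}": cfg.chrom_length
                     for i in range(cfg.n_chromosomes)}

    genes: list[GeneModel] = []
    feats: list[_Feature] = []
    feats_by_id: dict[str, _Feature] = {}
    acrs: list[AcrPeak] = []
    acr_truth_rows = []
    tes: list[BedInterval] = []
    transcripts: list[TranscriptCandidate] = []
    pair_rows, antisense_rows, link_rows = [], [], []

    for u, chrom, off in placed:
        for g in u.genes:
            start, end = g["start"] + off, g["end"] + off
            genes.append(
                GeneModel(
                    gene_id=g["id"], chrom=chrom, start=start, end=end,
                    strand=g["strand"], biotype=g["biotype"],
                    transcripts=[TranscriptModel(f"{g['id']}.1", start, end)],
                )
            )
        for f in u.features:
            feat = _Feature(
                f["id"], chrom, f["summit"] + off, f["strand"],
                f["peak_start"] + off, f["peak_end"] + off, f["role"],
                f["category"], host_gene=f.get("host"),
                partner=f.get("partner"),
            )
            feat._gen = f  # builder metadata (amp_scale, corr_to, target_r)
            feats.append(feat)
            feats_by_id[feat.fid] = feat
        for a in u.acrs:
            acrs.append(
                AcrPeak(peak_id=a["id"], chrom=chrom, start=a["start"] + off,
                        end=a["end"] + off, summit=a["summit"] + off)
            )
            acr_truth_rows.append(dict(acr_id=a["id"], truth_label=a["label"]))
        for t in u.tes:
            tes.append(
                BedInterval(chrom, t["start"] + off, t["end"] + off,
                            t["id"], 0.0, "+")
            )
        for tx in u.transcripts:
            transcripts.append(
                TranscriptCandidate(tx_id=tx["id"], chrom=chrom,
                                    start=tx["start"] + off,
                                    end=tx["end"] + off, strand=tx["strand"],
                                    source="simulated")
            )
        if hasattr(u, "pair"):
            pair_rows.append(dict(u.pair))
        if hasattr(u, "antisense"):
            antisense_rows.append(dict(u.antisense))
        if hasattr(u, "enhancer_link"):
            link_rows.append(dict(u.enhancer_link))

    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    annotation = GenomeAnnotation(
        chromosomes=sorted(chrom_lengths.items()), genes=genes
    )

    # -- expression: topological pass (bases before correlated partners) ---
    planner = _ExpressionPlanner(rng, cfg)
    for feat in feats:
        meta = feat._gen
        if meta["corr_to"] is None:
            planner.independent(feat, meta["amp_scale"])
    for feat in feats:
        meta = feat._gen
        if meta["corr_to"] is None:
            continue
        src = meta["corr_to"]
        if isinstance(src, tuple):
            base = np.sum([feats_by_id[s].counts_tc for s in src], axis=0)
        else:
            base = feats_by_id[src].counts_tc
        if meta["target_r"] is None:
            planner.independent(feat, meta["amp_scale"])
        else:
            planner.correlated(feat, base, meta["target_r"],
                               meta["amp_scale"])

    # -- exosome sensitivity and mutant counts ----------------------------
    nc_feats = [f for f in feats if f.truth_category != "mRNA"]
    n_sens = min(cfg.n_exosome_sensitive, len(nc_feats))
    order = rng.permutation(len(nc_feats))
    sens_feats = [nc_feats[i] for i in order[:n_sens]]
    # the two mutants share ~70% of their sensitive sets
    n_shared = int(round(0.7 * n_sens))
    sens_by_mutant = {m: set() for m in cfg.mutants}
    for i, f in enumerate(sens_feats):
        if i < n_shared:
            for m in cfg.mutants:
                sens_by_mutant[m].add(f.fid)
        else:
            m = cfg.mutants[i % len(cfg.mutants)]
            sens_by_mutant[m].add(f.fid)

    lfc = {}
    for f in feats:
        for m in cfg.mutants:
            if f.fid in sens_by_mutant.get(m, ()):
                lfc[(f.fid, m)] = float(rng.uniform(2.0, 5.0))
            else:
                lfc[(f.fid, m)] = 0.0

    samples = cfg.samples
    counts = np.zeros((len(feats), len(samples)), dtype=int)
    for i, f in enumerate(feats):
        counts[i, : len(cfg.timepoints)] = f.counts_tc
        base_mu = f.mean_tc[_L57_INDEX]
        for j, m in enumerate(cfg.mutants):
            mu = base_mu * 2.0 ** lfc[(f.fid, m)]
            counts[i, len(cfg.timepoints) + j] = _nb_draw(
                rng, np.array([mu]), cfg.expression_dispersion
            )[0]
    counts_df = pd.DataFrame(counts, index=[f.fid for f in feats],
                             columns=samples)

    # -- tracks ------------------------------------------------------------
    p = cfg.summit_dispersion
    tracks: dict[str, SignalTrack] = {}
    for j, s in enumerate(samples):
        track = SignalTrack(chrom_lengths)
        for i, f in enumerate(feats):
            n = int(counts[i, j])
            if n == 0:
                continue
            mag = rng.geometric(1.0 - p, size=n) - 1
            sign = rng.choice((-1, 1), size=n)
            pos = f.summit + mag * sign
            pos = np.clip(pos, f.peak_start, f.peak_end - 1)
            track.add_at(f.chrom, f.strand, pos)
        if cfg.noise_rate > 0:
            for chrom, length in chrom_lengths.items():
                for strand in ("+", "-"):
                    n_bg = rng.poisson(cfg.noise_rate * length / 1000.0)
                    if n_bg:
                        track.add_at(chrom, strand,
                                     rng.integers(0, length, size=n_bg))
        tracks[s] = track

    # truth invariant: every planted TSS carries pooled signal at its summit
    pooled = SignalTrack.pooled(tracks.values())
    for i, f in enumerate(feats):
        if pooled.values(f.chrom, f.strand, f.summit, f.summit + 1)[0] == 0:
            tracks[samples[_L57_INDEX]].add(f.chrom, f.strand, f.summit,
                                            f.summit + 1, 1.0)
            counts_df.iloc[i, _L57_INDEX] += 1

    # -- peaks -------------------------------------------------------------
    peaks = [
        TssPeak(peak_id=f.fid, chrom=f.chrom, start=f.peak_start,
                end=f.peak_end, strand=f.strand, summit=f.summit)
        for f in feats
    ]

    # -- DE tables ---------------------------------------------------------
    simple_cpm = counts_df / counts_df.sum(axis=0) * 1e6
    max_cpm = simple_cpm.max(axis=1)
    de_tables: dict[str, pd.DataFrame] = {}
    exo_rows = []
    for m in cfg.mutants:
        rows = []
        for f in nc_feats:
            planted = lfc[(f.fid, m)]
            if planted > 0:
                l2fc = planted
                q = float(rng.uniform(1e-6, 0.01))
            else:
                l2fc = float(rng.uniform(-0.6, 0.6))
                q = float(rng.uniform(0.2, 0.95))
            mx = float(max_cpm[f.fid])
            rows.append(dict(feature_id=f.fid, log2FC=round(l2fc, 4),
                             qvalue=q, max_cpm=round(mx, 4)))
            call = "unclassified"
            if l2fc >= 2 and q < 0.05:
                call = "sensitive"
            elif abs(l2fc) < 1 and q > 0.05 and mx > 1:
                call = "insensitive"
            exo_rows.append(dict(assay="csRNA", mutant=m, feature_id=f.fid,
                                 planted_lfc=round(l2fc, 4), qvalue=q,
                                 truth_call=call))
        de_tables[f"csRNA_{m}"] = pd.DataFrame(rows)

    # small totalRNA tables over the reconstructable transcripts
    tx_sens = {t.tx_id for t in transcripts[: max(1, len(transcripts) // 3)]}
    for m in cfg.mutants:
        rows = []
        for t in transcripts:
            if t.tx_id in tx_sens:
                l2fc = float(rng.uniform(2.0, 5.0))
                q = float(rng.uniform(1e-6, 0.01))
            else:
                l2fc = float(rng.uniform(-0.6, 0.6))
                q = float(rng.uniform(0.2, 0.95))
            mx = float(rng.uniform(0.5, 50.0))
            rows.append(dict(feature_id=t.tx_id, log2FC=round(l2fc, 4),
                             qvalue=q, max_tpm=round(mx, 4)))
            call = "unclassified"
            if l2fc >= 2 and q < 0.05:
                call = "sensitive"
            elif abs(l2fc) < 1 and q > 0.05 and mx > 0.1:
                call = "insensitive"
            exo_rows.append(dict(assay="totalRNA", mutant=m,
                                 feature_id=t.tx_id,
                                 planted_lfc=round(l2fc, 4), qvalue=q,
                                 truth_call=call))
        de_tables[f"totalRNA_{m}"] = pd.DataFrame(rows)

    # -- truth tables ------------------------------------------------------
    peak_truth = pd.DataFrame(
        [dict(peak_id=f.fid, chrom=f.chrom, summit=f.summit, strand=f.strand,
              role=f.role, truth_category=f.truth_category,
              host_gene=f.host_gene or "", partner=f.partner or "",
              planted_r="" if f.planted_r is None else round(f.planted_r, 4))
         for f in feats]
    )
    # re-derive the minus/plus members from post-flip strands
    def _orient(r):
        a, b = feats_by_id[r["minus"]], feats_by_id[r["plus"]]
        if r["kind"] == "convergent":
            # convergent: the "minus" slot holds the right-hand member
            m, p = (a, b) if a.strand == "-" else (b, a)
        else:
            m, p = (a, b) if a.strand == "-" else (b, a)
        return m.fid, p.fid

    pairs_truth = pd.DataFrame(
        [dict(kind=r["kind"], minus_peak=_orient(r)[0],
              plus_peak=_orient(r)[1], distance=r["distance"],
              planted_r="" if r["planted_r"] is None
              else round(r["planted_r"], 4))
         for r in pair_rows]
    )
    antisense_truth = pd.DataFrame(
        [dict(gene_id=r["gene"], sense_peak=r["sense"],
              antisense_peak=r["antisense"], truth_class=r["truth_class"],
              offset=r["offset"], gene_length=r["gene_length"])
         for r in antisense_rows]
    )
    links_truth = pd.DataFrame(
        [dict(source_peaks=",".join(r["sources"]), linked_gene=r["gene"],
              gene_peak=r["gene_peak"], planted_r=r["planted_r"])
         for r in link_rows]
    )
    source_rows = []
    for r in pair_rows:
        if r["kind"] == "ncTSS-ncTSS":
            source_rows.append(dict(kind="bidirectional_nc",
                                    peaks=f"{r['minus']},{r['plus']}"))
        elif r["kind"] == "convergent":
            source_rows.append(dict(kind="unidirectional_intergenic",
                                    peaks=r["minus"]))
            source_rows.append(dict(kind="unidirectional_intergenic",
                                    peaks=r["plus"]))
    for f in feats:
        if f.role == "unidirectional":
            source_rows.append(dict(kind="unidirectional_intergenic",
                                    peaks=f.fid))
    truth = TruthTables(
        peaks=peak_truth,
        pairs=pairs_truth,
        antisense=antisense_truth,
        enhancer_links=links_truth,
        enhancer_sources=pd.DataFrame(source_rows),
        exosome=pd.DataFrame(exo_rows),
        acrs=pd.DataFrame(acr_truth_rows),
    )

    acrs.sort(key=lambda a: (a.chrom, a.start, a.peak_id))
    peaks.sort(key=lambda p: (p.chrom, p.start, p.peak_id))
    counts_df = counts_df.loc[[p.peak_id for p in peaks]]

    return SimulationResult(
        config=cfg, annotation=annotation, peaks=peaks, tracks=tracks,
        counts=counts_df, de_tables=de_tables, acrs=acrs, te_intervals=tes,
        transcripts=transcripts, truth=truth,
    )


# ---------------------------------------------------------------------------
# Fixture emission
# ---------------------------------------------------------------------------


def _write_gff3(annotation: GenomeAnnotation, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in annotation.chromosomes:
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for g in annotation.genes:
            ftype = "gene"
            attrs = f"ID={g.gene_id};biotype={g.biotype}"
            fh.write(
                f"{g.chrom}\t.\t{ftype}\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for tx in g.transcripts:
                fh.write(
                    f"{g.chrom}\t.\tmRNA\t{tx.start + 1}\t{tx.end}\t.\t"
                    f"{g.strand}\t.\tID={tx.tx_id};Parent={g.gene_id}\n"
                )


def emit_fixture(out_dir: str, preset: str = "mini",
                 seed: int = 0,
                 config: Optional[SimulationConfig] = None) -> SimulationResult:
    """Write the full on-disk bundle consumed by the CLI; returns the result."""
    if config is None:
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}")
        config = SimulationConfig(seed=seed, **PRESETS[preset])
    os.makedirs(out_dir, exist_ok=True)
    sim = simulate(config)

    config.to_yaml(os.path.join(out_dir, "config.yaml"))
    _write_gff3(sim.annotation, os.path.join(out_dir, "annotation.gff3"))
    write_bed(sim.peaks, os.path.join(out_dir, "tss_peaks.bed"))
    write_bed(sim.acrs, os.path.join(out_dir, "acr_peaks.bed"))
    write_bed(sim.te_intervals, os.path.join(out_dir, "te.bed"))
    write_bed(sim.transcripts, os.path.join(out_dir, "transcripts.bed"))
    write_matrix(
        ExpressionMatrix(sim.counts, mutant_samples=list(config.mutants)),
        os.path.join(out_dir, "counts.tsv"),
    )
    for s, track in sim.tracks.items():
        write_bedgraph_pair(
            track,
            os.path.join(out_dir, f"signal_{s}_plus.bedGraph"),
            os.path.join(out_dir, f"signal_{s}_minus.bedGraph"),
        )
    for name, df in sim.de_tables.items():
        write_de_table(df, os.path.join(out_dir, f"de_{name}.tsv"))
    for name in ("peaks", "pairs", "antisense", "enhancer_links",
                 "enhancer_sources", "exosome", "acrs"):
        getattr(sim.truth, name).to_csv(
            os.path.join(out_dir, f"truth_{name}.tsv"), sep="\t", index=False
        )
    return sim
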