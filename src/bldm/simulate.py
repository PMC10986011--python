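"""Fully synthetic bisulfite-haplotype cohorts with planted truth.

The generator emulates the data a blood-leukocyte RRBS study produces, at the
level this package consumes it: read-level methylation haplotypes over a
reference CpG set, plus a clinical sample sheet. The generative model is

* blocks of 3-6 CpGs laid out along one chromosome, far enough apart that no
  read spans two blocks;
* per block a baseline methylation mean; a chosen subset of blocks receives a
  group mean shift (the planted differential markers), applied on the linear
  probability scale, with the shift direction chosen to stay inside [0, 1];
* per (sample, block) a methylation probability p drawn from a Beta with the
  group mean and a common concentration — between-sample biological variance;
* per block a negative-binomial read depth (clipped), occasional whole-block
  dropout, and a fraction of reads covering only a contiguous sub-range of
  the block's CpGs (RRBS clipping);
* within a read the first CpG is Bernoulli(p) and each subsequent CpG copies
  its left neighbour with probability ``concordance`` else resamples
  Bernoulli(p) — a Markov mechanism giving bimodal, block-like haplotypes as
  concordance -> 1 and noisy reads as concordance -> 0;
* clinical covariates: age ~ Normal, sex ~ Bernoulli, TI-RADS drawn from a
  label-conditional categorical (high sensitivity / moderate specificity,
  loosely mimicking ultrasonography operating points), nodule size ~
  log-normal with malignant nodules somewhat smaller (mirroring enrolment of
  suspicious micronodules). The TI-RADS model exists to exercise subgroup
  reporting, not as a claim about real ultrasonography.

Everything is driven by a single integer seed; identical configs produce
byte-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from bldm.io import (
    Cohort,
    CpGSite,
    HaplotypeRecord,
    SampleMeta,
    write_haplotype_file,
    write_sample_sheet,
    write_sites_bed,
)

logger = logging.getLogger(__name__)

TRUTH_SCHEMA_VERSION = 1


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Cohort sizes default to the three-phase design of the motivating clinical
    setting: 59 benign + 49 malignant discovery, 55 + 42 validation and
    53 + 35 independent-test samples.
    """

    n_blocks: int = 200
    cpgs_per_block: tuple[int, int] = (3, 6)  # inclusive range
    n_discovery: tuple[int, int] = (59, 49)  # (BTN, MTN)
    n_validation: tuple[int, int] = (55, 42)
    n_test: tuple[int, int] = (53, 35)
    baseline_mean_range: tuple[float, float] = (0.15, 0.85)
    baseline_concentration: float = 20.0
    n_differential: int = 30
    delta: float = 0.2  # group mean shift on the methylation probability
    effect_scale: str = "linear"  # or "logit"
    concordance: float = 0.8  # within-read Markov copy probability
    depth_mean: float = 30.0
    depth_dispersion: float = 5.0  # negative-binomial size parameter r
    depth_max: int = 500
    dropout: float = 0.05  # whole-block missingness probability
    partial_read_prob: float = 0.2
    tirads_probs: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            # categories 1..5; BTN spread over the scale (moderate specificity),
            # MTN concentrated at 4-5 (high sensitivity)
            "BTN": (0.05, 0.15, 0.25, 0.40, 0.15),
            "MTN": (0.00, 0.01, 0.01, 0.58, 0.40),
        }
    )
    size_mm_logmean: Mapping[str, float] = field(
        default_factory=lambda: {"BTN": float(np.log(12.0)), "MTN": float(np.log(8.0))}
    )
    size_mm_logsd: float = 0.55
    age_mean: float = 48.0
    age_sd: float = 12.0
    p_female: float = 0.7
    chrom: str = "chr1"
    block_spacing_bp: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.concordance <= 1:
            raise ValueError("concordance must be in [0, 1]")
        if not 0 <= self.dropout <= 1:
            raise ValueError("dropout must be in [0, 1]")
        if self.n_differential > self.n_blocks:
            raise ValueError("n_differential cannot exceed n_blocks")
        if self.effect_scale not in ("linear", "logit"):
            raise ValueError("effect_scale must be 'linear' or 'logit'")
        for pair in (self.n_discovery, self.n_validation, self.n_test):
            if min(pair) < 0:
                raise ValueError("cohort sizes must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tirads_probs"] = {k: list(v) for k, v in self.tirads_probs.items()}
        d["size_mm_logmean"] = dict(self.size_mm_logmean)
        return d


@dataclass
class TruthTable:
    """Planted ground truth: per-block flags/means and per-sample covariates."""

    blocks: pd.DataFrame  # index: block ordinal; columns incl. differential, means, span
    samples: pd.DataFrame  # index: sample_id; label, cohort, covariates
    config: SimConfig

    def differential_ids(self) -> list[int]:
        return list(self.blocks.index[self.blocks["differential"]])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema_version": TRUTH_SCHEMA_VERSION,
            "config": self.config.to_dict(),
            "blocks": self.blocks.reset_index().to_dict(orient="list"),
            "samples": self.samples.reset_index().to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        payload = json.loads(Path(path).read_text())
        cfg_d = payload["config"]
        cfg_d["cpgs_per_block"] = tuple(cfg_d["cpgs_per_block"])
        for k in ("n_discovery", "n_validation", "n_test", "baseline_mean_range"):
            cfg_d[k] = tuple(cfg_d[k])
        cfg_d["tirads_probs"] = {k: tuple(v) for k, v in cfg_d["tirads_probs"].items()}
        cfg = SimConfig(**cfg_d)
        blocks = pd.DataFrame(payload["blocks"]).set_index("block")
        samples = pd.DataFrame(payload["samples"]).set_index("sample_id")
        return cls(blocks=blocks, samples=samples, config=cfg)


def _logit_shift(mean: float, delta: float, sign: int) -> float:
    logit = np.log(mean / (1 - mean)) + sign * delta
    return float(1 / (1 + np.exp(-logit)))


def simulate_cohort(config: SimConfig) -> tuple[Cohort, TruthTable, list[CpGSite]]:
    """Generate a seeded synthetic cohort, its truth table and CpG reference."""
    rng = np.random.default_rng(config.seed)

    # --- block layout -----------------------------------------------------
    lo, hi = config.cpgs_per_block
    n_cpgs = rng.integers(lo, hi + 1, size=config.n_blocks)
    block_positions: list[np.ndarray] = []
    cursor = 1000
    for L in n_cpgs:
        gaps = rng.integers(10, 41, size=int(L) - 1) if L > 1 else np.empty(0, dtype=int)
        pos = cursor + np.concatenate([[0], np.cumsum(gaps)])
        block_positions.append(pos.astype(np.int64))
        cursor = int(pos[-1]) + config.block_spacing_bp
    sites = [CpGSite(config.chrom, int(p)) for pos in block_positions for p in pos]

    # --- per-block group means -------------------------------------------
    base = rng.uniform(*config.baseline_mean_range, size=config.n_blocks)
    differential = np.zeros(config.n_blocks, dtype=bool)
    diff_idx = rng.choice(config.n_blocks, size=config.n_differential, replace=False)
    differential[diff_idx] = True
    btn_mean = base.copy()
    mtn_mean = base.copy()
    for b in diff_idx:
        sign = 1 if base[b] <= 0.5 else -1
        if config.effect_scale == "linear":
            shifted = base[b] + sign * config.delta
            if not 0 <= shifted <= 1:
                warnings.warn(
                    f"block {b}: shifted mean {shifted:.3f} clipped into [0.01, 0.99]"
                )
                shifted = float(np.clip(shifted, 0.01, 0.99))
            mtn_mean[b] = shifted
        else:
            mtn_mean[b] = _logit_shift(base[b], config.delta, sign)

    # --- samples ----------------------------------------------------------
    metas: list[SampleMeta] = []
    for cohort_name, (n_btn, n_mtn) in (
        ("discovery", config.n_discovery),
        ("validation", config.n_validation),
        ("test", config.n_test),
    ):
        for label, n in (("BTN", n_btn), ("MTN", n_mtn)):
            for i in range(n):
                sid = f"{cohort_name[:3].upper()}_{label}_{i + 1:03d}"
                age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 18, 90))
                sex = "F" if rng.random() < config.p_female else "M"
                tirads = int(rng.choice(5, p=np.asarray(config.tirads_probs[label])) + 1)
                size_mm = float(
                    np.round(np.exp(rng.normal(config.size_mm_logmean[label], config.size_mm_logsd)), 1)
                )
                metas.append(
                    SampleMeta(
                        sample_id=sid,
                        label=label,
                        cohort=cohort_name,
                        age=round(age, 1),
                        sex=sex,
                        tirads=tirads,
                        size_mm=max(size_mm, 0.5),
                    )
                )

    # --- reads ------------------------------------------------------------
    kappa = config.baseline_concentration
    haplotypes: dict[str, list[HaplotypeRecord]] = {}
    for meta in metas:
        group_mean = mtn_mean if meta.label == "MTN" else btn_mean
        records: list[HaplotypeRecord] = []
        for b in range(config.n_blocks):
            if rng.random() < config.dropout:
                continue
            depth = int(
                rng.negative_binomial(
                    config.depth_dispersion,
                    config.depth_dispersion / (config.depth_dispersion + config.depth_mean),
                )
            )
            depth = min(depth, config.depth_max)
            if depth == 0:
                continue
            mu = group_mean[b]
            p = rng.beta(mu * kappa, (1 - mu) * kappa)
            L = int(n_cpgs[b])
            states = np.empty((depth, L), dtype=np.int8)
            states[:, 0] = rng.random(depth) < p
            for j in range(1, L):
                copy = rng.random(depth) < config.concordance
                fresh = rng.random(depth) < p
                states[:, j] = np.where(copy, states[:, j - 1], fresh)
            # RRBS clipping: some reads cover only a contiguous CpG sub-range
            offs = np.zeros(depth, dtype=np.int64)
            lens = np.full(depth, L, dtype=np.int64)
            if L > 1 and config.partial_read_prob > 0:
                partial = rng.random(depth) < config.partial_read_prob
                n_partial = int(partial.sum())
                if n_partial:
                    min_len = max(1, (L + 1) // 2)
                    plen = rng.integers(min_len, L + 1, size=n_partial)
                    poff = rng.integers(0, L - plen + 1)
                    lens[partial] = plen
                    offs[partial] = poff
            pos = block_positions[b]
            agg: dict[tuple[int, str], int] = {}
            for r in range(depth):
                off, ln = int(offs[r]), int(lens[r])
                pat = "".join("1" if v else "0" for v in states[r, off : off + ln])
                agg[(off, pat)] = agg.get((off, pat), 0) + 1
            for (off, pat), count in agg.items():
                records.append(
                    HaplotypeRecord(
                        chrom=config.chrom,
                        start=int(pos[off]),
                        end=int(pos[off + len(pat) - 1]) + 1,
                        pattern=pat,
                        count=count,
                        strand=".",
                    )
                )
        records.sort(key=lambda r: r.sort_key)
        haplotypes[meta.sample_id] = records

    cohort = Cohort(samples=metas, haplotypes=haplotypes)
    blocks_df = pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": [int(p[0]) for p in block_positions],
            "end": [int(p[-1]) + 1 for p in block_positions],
            "n_cpgs": n_cpgs.astype(int),
            "differential": differential,
            "btn_mean": btn_mean,
            "mtn_mean": mtn_mean,
        }
    )
    blocks_df.index.name = "block"
    samples_df = pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "label": m.label,
                "cohort": m.cohort,
                "age": m.age,
                "sex": m.sex,
                "tirads": m.tirads,
                "size_mm": m.size_mm,
            }
            for m in metas
        ]
    ).set_index("sample_id")
    truth = TruthTable(blocks=blocks_df, samples=samples_df, config=config)
    return cohort, truth, sites


def match_blocks_to_truth(mhbs, truth: TruthTable) -> dict[str, int]:
    """Map called block ids onto planted truth blocks by genomic overlap."""
    out: dict[str, int] = {}
    for mhb in mhbs:
        hits = truth.blocks[
            (truth.blocks["chrom"] == mhb.chrom)
            & (truth.blocks["start"] < mhb.end)
            & (truth.blocks["end"] > mhb.start)
        ]
        if len(hits) == 1:
            out[mhb.block_id] = int(hits.index[0])
        elif len(hits) > 1:  # overlap ties broken by larger intersection
            inter = np.minimum(hits["end"], mhb.end) - np.maximum(hits["start"], mhb.start)
            out[mhb.block_id] = int(hits.index[int(np.argmax(inter.to_numpy()))])
    return out


def write_cohort(
    cohort: Cohort,
    truth: TruthTable,
    sites: list[CpGSite],
    out_dir: str | Path,
    force: bool = False,
) -> None:
    """Emit per-sample mHap files, sample sheet, sites BED and truth JSON."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    (out / "haplotypes").mkdir(parents=True, exist_ok=True)
    for sid, records in sorted(cohort.haplotypes.items()):
        write_haplotype_file(records, out / "haplotypes" / f"{sid}.mhap.tsv")
    write_sample_sheet(cohort.samples, out / "samples.tsv")
    write_sites_bed(sites, out / "sites.bed")
    truth.to_json(out / "truth.json")
    logger.info("wrote %d samples to %s", len(cohort.samples), out)


def benchmark_scenarios() -> dict[str, SimConfig]:
    """Named presets spanning the study conditions used throughout the tests.

    ``paper_shaped`` uses the three-phase cohort sizes with a moderate planted
    effect; ``easy`` raises the effect to 0.3; ``hard`` lowers it to 0.1 at
    10X depth; ``null`` plants no differential blocks at all.
    """
    return {
        "paper_shaped": SimConfig(delta=0.2, seed=20_240_402),
        "easy": SimConfig(delta=0.3, seed=20_240_402),
        "hard": SimConfig(delta=0.1, depth_mean=10.0, seed=20_240_402),
        "null": SimConfig(delta=0.0, n_differential=0, seed=20_240_402),
    }
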