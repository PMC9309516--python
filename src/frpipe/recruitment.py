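"""Fragment recruitment: best hits, ANI, coverage sections, RSD, presence.

Plant-depleted reads are aligned against a manifest of reference genomes;
for each read only the best qualifying hit (>= 60% identity and >= 60%
query coverage) is kept. Per genome, the recruited reads yield

* ``n_reads`` — how many reads the genome recruits;
* ``ani`` — the unweighted mean percent identity of those reads (a
  read-based average nucleotide identity, not a genome-to-genome ANI);
* ``section_counts`` — reads per tenth of the concatenated genome axis;
* ``rsd`` — the relative standard deviation of the ten section counts
  (sample standard deviation divided by mean), a coverage-uniformity
  statistic: reads piling into one genome region inflate it;
* an identity histogram and a two-cloud (bimodality) flag.

A species is called present when its genome recruits at least
``min_reads`` (default 1000) reads with RSD strictly below ``max_rsd``
(default 0.8). The reported identity band follows the recruited-read ANI,
except that when two read clouds are detected and the high cloud averages
above 90% identity the band follows the high cloud — the lower cloud then
reflects reads from a related species missing from the database.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .io import contig_offsets

DEFAULT_MIN_IDENTITY = 60.0
DEFAULT_MIN_COVERAGE = 60.0
DEFAULT_MIN_READS = 1000
DEFAULT_MAX_RSD = 0.8
N_SECTIONS = 10

IDENTITY_BIN_EDGES = np.arange(60.0, 101.0)  # 1%-wide bins spanning [60, 100]

#: ANI band labels, highest first, with their inclusive lower bounds.
ANI_BANDS = (
    ("95-100", 95.0),
    ("90-95", 90.0),
    ("80-90", 80.0),
    ("70-80", 70.0),
    ("below-70", -math.inf),
)


@dataclass
class CloudSummary:
    n_reads: int
    mean_identity: float


@dataclass
class RecruitmentProfile:
    """Per-genome aggregate of the recruited reads."""

    genome_id: str
    n_reads: int
    ani: float  # nan when no reads
    section_counts: np.ndarray
    rsd: float  # nan when no reads
    identity_histogram: np.ndarray
    two_clouds: bool
    cloud_summaries: list[CloudSummary] = field(default_factory=list)


@dataclass
class PresenceCall:
    species: str
    genome_id: str
    present: bool
    ani_band: str
    two_cloud_flag: bool
    relative_abundance: float
    fail_reasons: frozenset[str]
    n_reads: int = 0
    ani: float = float("nan")
    rsd: float = float("nan")


# ---------------------------------------------------------------------------
# per-operation pieces

def best_hits(
    alignments: pd.DataFrame,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Keep at most one qualifying alignment per read.

    After the identity/coverage filter the winner per read has the highest
    bit score; ties break on higher identity, then lexicographically
    smallest genome id (a deterministic convention).
    """
    ok = alignments[
        (alignments["pident"] >= min_identity) & (alignments["qcov"] >= min_coverage)
    ]
    if ok.empty:
        return ok
    ranked = ok.sort_values(
        ["qseqid", "bitscore", "pident", "genome_id"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    return ranked.drop_duplicates("qseqid", keep="first")


def section_counts(
    total_length: int, midpoints: np.ndarray, n_sections: int = N_SECTIONS
) -> np.ndarray:
    """Count read midpoints per genome tenth on the concatenated axis.

    The axis [0, L) is cut into ``n_sections`` half-open intervals of width
    L // n_sections; the last interval absorbs the remainder.
    """
    if total_length < n_sections:
        raise ValueError(f"genome length {total_length} shorter than {n_sections}")
    midpoints = np.asarray(midpoints, dtype=float)
    if midpoints.size and (midpoints.min() < 0 or midpoints.max() >= total_length):
        raise ValueError("read midpoint outside [0, genome length)")
    width = total_length // n_sections
    idx = np.minimum((midpoints // width).astype(int), n_sections - 1)
    return np.bincount(idx, minlength=n_sections)


def compute_rsd(counts: np.ndarray, ddof: int = 1) -> float:
    """Sample standard deviation of the section counts over their mean.

    ``ddof=1`` (the default) uses the n−1 sample standard deviation;
    ``ddof=0`` switches to the population form. Returns nan (a flagged
    missing value) when no reads were recruited.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return float("nan")
    mean = counts.mean()
    return float(counts.std(ddof=ddof) / mean)


def compute_ani(identities: np.ndarray) -> float:
    """Unweighted mean percent identity; nan when no reads."""
    identities = np.asarray(identities, dtype=float)
    if identities.size == 0:
        return float("nan")
    return float(identities.mean())


def identity_histogram(identities: np.ndarray) -> np.ndarray:
    """Counts per 1% identity bin over [60, 100] (40 bins, last closed)."""
    identities = np.asarray(identities, dtype=float)
    hist, _ = np.histogram(identities, bins=IDENTITY_BIN_EDGES)
    # np.histogram closes the last bin, so identity 100.0 lands in [99, 100].
    return hist


def detect_clouds(
    hist: np.ndarray,
    min_peak_mass: float = 0.05,
    valley_ratio: float = 0.5,
    min_cloud_reads: int = 50,
) -> tuple[bool, list[CloudSummary]]:
    """Flag a bimodal identity distribution (two read clouds).

    The histogram is smoothed with a centered 3-bin moving average; local
    maxima whose smoothed height reaches ``min_peak_mass`` of the recruited
    reads count as peaks. Two clouds are reported when two such peaks are
    separated by a valley no higher than ``valley_ratio`` of the smaller
    peak, and each side of the deepest valley holds at least
    ``min_cloud_reads`` reads (a support floor against sparse histograms).
    Summaries (read count, mean identity from bin centers) cover both sides
    of the deepest valley.
    """
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    if total == 0:
        return False, []
    smooth = np.convolve(hist, np.ones(3) / 3.0, mode="same")
    # pad so a cloud hugging either histogram edge still registers as a peak
    padded = np.concatenate(([-1.0], smooth, [-1.0]))
    peaks, _ = find_peaks(padded, height=min_peak_mass * total)
    peaks = peaks - 1
    if len(peaks) < 2:
        return False, []

    best: tuple[float, int, int, int] | None = None  # (depth score, lo, hi, valley)
    for i in range(len(peaks) - 1):
        for j in range(i + 1, len(peaks)):
            lo, hi = peaks[i], peaks[j]
            seg = smooth[lo : hi + 1]
            v_rel = int(np.argmin(seg[1:-1])) + 1 if len(seg) > 2 else None
            if v_rel is None:
                continue
            valley = smooth[lo + v_rel]
            smaller = min(smooth[lo], smooth[hi])
            if valley <= valley_ratio * smaller:
                score = smaller - valley
                if best is None or score > best[0]:
                    best = (score, lo, hi, lo + v_rel)
    if best is None:
        return False, []

    _, _, _, valley_idx = best
    centers = IDENTITY_BIN_EDGES[:-1] + 0.5
    low_mask = np.arange(len(hist)) <= valley_idx
    sides = []
    for mask in (low_mask, ~low_mask):
        n = int(hist[mask].sum())
        mean = float((hist[mask] * centers[mask]).sum() / n) if n else float("nan")
        sides.append(CloudSummary(n, mean))
    if any(s.n_reads < min_cloud_reads for s in sides):
        return False, []
    return True, sides


# ---------------------------------------------------------------------------
# profiles and presence calls

def build_profiles(
    best: pd.DataFrame, manifest: pd.DataFrame, contig_table: pd.DataFrame
) -> dict[str, RecruitmentProfile]:
    """Aggregate best hits into one RecruitmentProfile per manifest genome."""
    offsets = contig_offsets(contig_table)
    off_map = dict(zip(offsets["contig_id"], offsets["offset"]))
    lengths = dict(zip(manifest["genome_id"], manifest["total_length"]))

    profiles: dict[str, RecruitmentProfile] = {}
    groups = dict(tuple(best.groupby("genome_id"))) if not best.empty else {}
    for genome_id, total_length in lengths.items():
        sub = groups.get(genome_id)
        if sub is None or sub.empty:
            profiles[genome_id] = RecruitmentProfile(
                genome_id, 0, float("nan"), np.zeros(N_SECTIONS, dtype=int),
                float("nan"), np.zeros(len(IDENTITY_BIN_EDGES) - 1, dtype=int),
                False, [],
            )
            continue
        missing = set(sub["subject_contig"]) - set(off_map)
        if missing:
            raise ValueError(f"alignments reference unknown contigs: {sorted(missing)[:3]}")
        off = sub["subject_contig"].map(off_map).to_numpy(dtype=float)
        lo = np.minimum(sub["sstart"], sub["send"]).to_numpy(dtype=float)
        hi = np.maximum(sub["sstart"], sub["send"]).to_numpy(dtype=float)
        mid = off + (lo - 1 + hi) / 2.0  # 1-based inclusive -> 0-based axis
        counts = section_counts(int(total_length), mid)
        ids = sub["pident"].to_numpy(dtype=float)
        hist = identity_histogram(ids)
        two, summaries = detect_clouds(hist)
        profiles[genome_id] = RecruitmentProfile(
            genome_id, len(sub), compute_ani(ids), counts, compute_rsd(counts),
            hist, two, summaries,
        )
    return profiles


def ani_band(value: float) -> str:
    if math.isnan(value):
        return "below-70"
    for label, lower in ANI_BANDS:
        if value >= lower:
            return label
    return "below-70"  # pragma: no cover


def relative_abundance(n_reads: int, total_sample_reads: int) -> float:
    """Percent of the sample's quality-trimmed reads recruited by a genome."""
    if total_sample_reads <= 0:
        raise ValueError("total_sample_reads must be positive")
    return 100.0 * n_reads / total_sample_reads


def call_presence(
    profile: RecruitmentProfile,
    total_sample_reads: int,
    species: str | None = None,
    min_reads: int = DEFAULT_MIN_READS,
    max_rsd: float = DEFAULT_MAX_RSD,
) -> PresenceCall:
    """Apply the presence rule and assign the identity band."""
    fails = set()
    if profile.n_reads < min_reads:
        fails.add("too_few_reads")
    if not (profile.rsd < max_rsd):  # nan fails too, but only matters with reads
        if profile.n_reads > 0 and not math.isnan(profile.rsd) and profile.rsd >= max_rsd:
            fails.add("rsd_too_high")

    band_source = profile.ani
    if profile.two_clouds and profile.cloud_summaries:
        high = max(profile.cloud_summaries, key=lambda c: c.mean_identity)
        if high.mean_identity > 90.0:
            band_source = high.mean_identity
    return PresenceCall(
        species=species or profile.genome_id,
        genome_id=profile.genome_id,
        present=not fails,
        ani_band=ani_band(band_source),
        two_cloud_flag=profile.two_clouds,
        relative_abundance=relative_abundance(profile.n_reads, total_sample_reads),
        fail_reasons=frozenset(fails),
        n_reads=profile.n_reads,
        ani=profile.ani,
        rsd=profile.rsd,
    )


def presence_table(
    profiles: dict[str, RecruitmentProfile],
    manifest: pd.DataFrame,
    sample_id: str,
    total_sample_reads: int,
    min_reads: int = DEFAULT_MIN_READS,
    max_rsd: float = DEFAULT_MAX_RSD,
    min_band: float = 70.0,
) -> pd.DataFrame:
    """Per-sample presence-call table in the published layout.

    One row per manifest genome with the identity band, the two-cloud
    asterisk column, and the relative read percentage. Calls whose band
    falls below ``min_band`` are retained in the frame but flagged
    ``reportable=False`` (the published tables only list bands >= 70%).
    """
    meta = manifest.set_index("genome_id")
    rows = []
    for genome_id, prof in profiles.items():
        call = call_presence(
            prof, total_sample_reads, species=str(meta.loc[genome_id, "species"]),
            min_reads=min_reads, max_rsd=max_rsd,
        )
        band_lower = dict(ANI_BANDS).get(call.ani_band, -math.inf)
        rows.append({
            "sample_id": sample_id,
            "group": meta.loc[genome_id, "group_label"],
            "species": call.species,
            "genome_id": genome_id,
            "present": call.present,
            "ani": round(call.ani, 2) if not math.isnan(call.ani) else float("nan"),
            "ani_band": call.ani_band,
            "two_clouds": "*" if call.two_cloud_flag else "",
            "relative_abundance": round(call.relative_abundance, 2),
            "n_reads": call.n_reads,
            "rsd": round(call.rsd, 3) if not math.isnan(call.rsd) else float("nan"),
            "fail_reasons": ",".join(sorted(call.fail_reasons)),
            "reportable": call.present and band_lower >= min_band,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rollups over species-by-sample relative abundance tables

def rollup_abundance(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample totals/species counts and per-group (class/phylum) totals.

    ``table`` is long format with columns (sample_id, group, species,
    percent); only strictly positive cells count as reported species.
    Returns (per_sample, per_group) frames: per_sample has total_percent
    and n_species; per_group has one total per (sample_id, group).
    """
    need = {"sample_id", "group", "species", "percent"}
    if not need <= set(table.columns):
        raise ValueError(f"rollup table needs columns {sorted(need)}")
    pos = table[table["percent"] > 0]
    per_sample = (
        pos.groupby("sample_id")
        .agg(total_percent=("percent", "sum"), n_species=("species", "nunique"))
        .reset_index()
    )
    per_sample["total_percent"] = per_sample["total_percent"].round(2)
    per_group = (
        pos.groupby(["sample_id", "group"])["percent"].sum().round(2)
        .reset_index(name="total_percent")
    )
    return per_sample, per_group
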