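"""Synthetic ARC-C data with known planted structure.

Generates genomes, regulatory elements (REs), alternating typed chromatin
domains, binding-site sets and read pairs, so that every pipeline stage can
be tested against ground truth. Pair generation factorizes like the calling
model: the probability of a contact between bins i and j is proportional to

    b_i * b_j * F(|m_i - m_j|) * boost(i, j)

where b is a per-bin accessibility bias (elevated where REs cover the bin,
with optional lognormal noise), F a power-law distance decay d^(-gamma),
and boost a multiplicative structure term: planted loops (anchor pairs with
a fold boost), within-domain enrichment e, and same-type compartment
preference r. End strands are independent and uniform for ligation pairs;
an optional unligated component adds short forward-reverse pairs, and PCR
duplicates are injected at a configured rate. Everything is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve


def _default_chroms() -> dict[str, int]:
    return {"chrS1": 5_000_000, "chrS2": 5_000_000}


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset; ``seed`` is mandatory."""

    seed: int
    chrom_sizes: dict[str, int] = field(default_factory=_default_chroms)
    bin_width: int = 500
    n_pairs: int = 2_000_000
    # distance decay
    decay_exponent: float = 1.0
    distance_law: str = "powerlaw"  # powerlaw | flat | uniform
    uniform_range: tuple[int, int] = (601, 100_000)
    # accessibility
    re_density: float = 0.21
    re_width_range: tuple[int, int] = (150, 800)
    # calibrated so that REs covering ~21% of the genome capture ~44% of ends
    re_accessibility_fold: float = 4.3
    bias_lognorm_sigma: float = 0.0
    # planted loops
    n_loops: int = 0
    loop_fold: float = 8.0
    loop_distance_range: tuple[int, int] = (2_000, 100_000)
    # domains / compartments
    domain_size_range: tuple[int, int] = (100_000, 300_000)
    domain_enrichment: float = 1.0
    compartment_preference: float = 1.0
    # binding sites
    n_site_sets: int = 0
    sites_per_set: int = 400
    site_width: int = 200
    # read-level nuisance
    nonligated_fraction: float = 0.0
    nonligated_range: tuple[int, int] = (50, 500)
    trans_fraction: float = 0.0
    duplicate_rate: float = 0.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("re_accessibility_fold", "loop_fold", "domain_enrichment",
                     "compartment_preference"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_pairs <= 0:
            raise ValueError("n_pairs must be positive")


@dataclass
class Annotation:
    """Simulated annotation tracks (all BED-style DataFrames)."""

    res: pd.DataFrame
    domains: pd.DataFrame
    site_sets: dict[str, pd.DataFrame]
    chrom_sizes: dict[str, int]


@dataclass
class GroundTruth:
    """What was planted: per-bin bias, loops, domain labels, duplicates."""

    bias: dict[str, np.ndarray]
    loops: pd.DataFrame
    domains: pd.DataFrame
    expected_orientation: dict[str, float]
    n_duplicates: int = 0
    config: SimConfig | None = None


def _n_bins(length: int, bw: int) -> int:
    return (length + bw - 1) // bw


def simulate_annotation(config: SimConfig) -> Annotation:
    """REs, alternating typed domains covering each chromosome, and site sets
    placed inside REs. Deterministic given config.seed."""
    rng = np.random.default_rng(config.seed)
    re_rows = []
    dom_rows = []
    wlo, whi = config.re_width_range
    mean_w = (wlo + whi) / 2
    for chrom, length in config.chrom_sizes.items():
        if config.re_density > 0:
            if config.re_density >= 0.9:
                raise ValueError("re_density too high to place non-overlapping REs")
            mean_gap = mean_w * (1 - config.re_density) / config.re_density
            cursor = 0
            while True:
                gap = int(rng.exponential(mean_gap)) + 1
                width = int(rng.integers(wlo, whi + 1))
                start = cursor + gap
                if start + width > length:
                    break
                re_rows.append((chrom, start, start + width))
                cursor = start + width
        # alternating domains with no gaps
        dlo, dhi = config.domain_size_range
        pos = 0
        t = int(rng.integers(0, 2))
        while pos < length:
            size = int(rng.integers(dlo, dhi + 1))
            end = min(pos + size, length)
            dom_rows.append((chrom, pos, end, ("active", "H3K27me3")[t]))
            pos = end
            t = 1 - t
    res = pd.DataFrame(re_rows, columns=["chrom", "start", "end"])
    domains = pd.DataFrame(dom_rows, columns=["chrom", "start", "end", "type"])
    site_sets = {}
    if config.n_site_sets > 0:
        if len(res) < config.sites_per_set:
            raise ValueError("not enough REs to place the requested binding sites")
        for s in range(config.n_site_sets):
            take = np.sort(rng.choice(len(res), size=config.sites_per_set, replace=False))
            sub = res.iloc[take]
            mid = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
            half = np.minimum(config.site_width, sub["end"].to_numpy() - sub["start"].to_numpy()) // 2
            sites = pd.DataFrame(
                {
                    "chrom": sub["chrom"].to_numpy(),
                    "start": mid - half,
                    "end": mid + np.maximum(half, 1),
                }
            ).sort_values(["chrom", "start"]).reset_index(drop=True)
            site_sets[f"factor{s:03d}"] = sites
    return Annotation(res=res, domains=domains, site_sets=site_sets,
                      chrom_sizes=dict(config.chrom_sizes))


def _bin_bias(config: SimConfig, ann: Annotation, chrom: str, rng) -> np.ndarray:
    length = config.chrom_sizes[chrom]
    bw = config.bin_width
    n = _n_bins(length, bw)
    cov = np.zeros(n)
    sub = ann.res[ann.res["chrom"] == chrom] if len(ann.res) else ann.res
    if len(sub):
        mask = np.zeros(length, dtype=np.float32)
        for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            mask[s:e] = 1.0
        edges = np.arange(0, length, bw)
        cov = np.add.reduceat(mask, edges) / np.diff(np.append(edges, length))
    b = 1.0 + (config.re_accessibility_fold - 1.0) * cov
    if config.bias_lognorm_sigma > 0:
        s = config.bias_lognorm_sigma
        b = b * rng.lognormal(mean=-s * s / 2, sigma=s, size=n)
    return b / b.mean()


def _domain_codes(ann: Annotation, chrom: str, bw: int, n: int):
    sub = ann.domains[ann.domains["chrom"] == chrom].reset_index(drop=True)
    mids = np.arange(n) * bw + bw / 2
    dom_id = np.searchsorted(sub["end"].to_numpy(), mids, side="right")
    dom_id = np.clip(dom_id, 0, len(sub) - 1)
    type_code = (sub["type"].to_numpy() == "H3K27me3").astype(np.int8)[dom_id]
    return dom_id, type_code


def _decay_weights(config: SimConfig, n: int) -> np.ndarray:
    bw = config.bin_width
    k = np.arange(n, dtype=float)
    if config.distance_law == "powerlaw":
        F = np.empty(n)
        F[1:] = (k[1:] * bw) ** (-config.decay_exponent)
        F[0] = F[1] if n > 1 else 1.0
        return F
    if config.distance_law == "flat":
        return np.ones(n)
    raise ValueError(f"unknown distance law {config.distance_law!r}")


def _autocorr(x: np.ndarray) -> np.ndarray:
    """c[k] = sum_i x[i] * x[i+k], via FFT convolution."""
    full = fftconvolve(x, x[::-1])
    return full[len(x) - 1 :]


def _plant_loops(config: SimConfig, rng, chrom_bins: dict[str, int]) -> pd.DataFrame:
    if config.n_loops == 0:
        return pd.DataFrame(columns=["chrom", "bin1", "bin2", "fold"])
    chroms = list(chrom_bins)
    lengths = np.array([chrom_bins[c] for c in chroms], dtype=float)
    bw = config.bin_width
    klo = max(1, config.loop_distance_range[0] // bw)
    khi = max(klo + 1, config.loop_distance_range[1] // bw)
    rows = set()
    out = []
    guard = 0
    while len(out) < config.n_loops:
        guard += 1
        if guard > 100 * config.n_loops:
            raise RuntimeError("could not place the requested number of loops")
        c = chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]
        n = chrom_bins[c]
        k = int(np.exp(rng.uniform(np.log(klo), np.log(min(khi, n - 1)))))
        if k < 1 or k >= n:
            continue
        i = int(rng.integers(0, n - k))
        key = (c, i, i + k)
        if key in rows:
            continue
        rows.add(key)
        out.append({"chrom": c, "bin1": i, "bin2": i + k, "fold": config.loop_fold})
    return pd.DataFrame(out)


def simulate_pairs(config: SimConfig, ann: Annotation) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw read pairs from the factorized contact model.

    Returns the pair table (same columns the classifier consumes) and the
    ground truth. The emitted count equals ``config.n_pairs`` before
    duplicate injection; injected duplicates are appended and counted in the
    truth.
    """
    rng = np.random.default_rng(config.seed + 1)
    bw = config.bin_width
    chrom_bins = {c: _n_bins(L, bw) for c, L in config.chrom_sizes.items()}
    bias = {c: _bin_bias(config, ann, c, rng) for c in config.chrom_sizes}
    loops = _plant_loops(config, rng, chrom_bins)

    chroms = list(config.chrom_sizes)
    lengths = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    n_trans = int(round(config.n_pairs * config.trans_fraction))
    n_cis_total = config.n_pairs - n_trans
    shares = lengths / lengths.sum()
    per_chrom = np.floor(n_cis_total * shares).astype(int)
    per_chrom[0] += n_cis_total - per_chrom.sum()

    frames = []
    e = config.domain_enrichment
    r = config.compartment_preference
    structured = (e != 1.0) or (r != 1.0)
    for c, n_c in zip(chroms, per_chrom):
        if n_c == 0:
            continue
        n_non = int(round(n_c * config.nonligated_fraction))
        n_lig = n_c - n_non
        if config.distance_law == "uniform":
            frames.append(_uniform_ligation(config, rng, c, n_lig))
        else:
            frames.append(
                _ligation_pairs(config, rng, c, n_lig, bias[c], ann, loops, structured)
            )
        if n_non:
            frames.append(_nonligated_pairs(config, rng, c, n_non))
    if n_trans:
        frames.append(_trans_pairs(config, rng, chroms, lengths, n_trans))
    pairs = pd.concat(frames, ignore_index=True)
    # randomize end order (the classifier must not rely on it)
    flip = rng.random(len(pairs)) < 0.5
    for a, b_ in (("chrom1", "chrom2"), ("pos1", "pos2"), ("strand1", "strand2"),
                  ("mapq1", "mapq2"), ("nm1", "nm2")):
        va, vb = pairs[a].to_numpy().copy(), pairs[b_].to_numpy().copy()
        pairs[a] = np.where(flip, vb, va)
        pairs[b_] = np.where(flip, va, vb)
    n_dup = int(round(len(pairs) * config.duplicate_rate))
    if n_dup:
        src = rng.integers(0, len(pairs), size=n_dup)
        pairs = pd.concat([pairs, pairs.iloc[src]], ignore_index=True)
    pairs.insert(0, "read_id", [f"sim{i:09d}" for i in range(len(pairs))])
    mids = {c: np.arange(chrom_bins[c]) * bw + bw // 2 for c in chroms}
    if len(loops):
        loops = loops.assign(
            pos1=[mids[c][b] for c, b in zip(loops["chrom"], loops["bin1"])],
            pos2=[mids[c][b] for c, b in zip(loops["chrom"], loops["bin2"])],
        )
    lig_frac = 1.0 - config.nonligated_fraction
    expected_orientation = {
        o: 0.25 * lig_frac + (config.nonligated_fraction if o == "FR" else 0.0)
        for o in ("FF", "FR", "RF", "RR")
    }
    truth = GroundTruth(
        bias=bias,
        loops=loops,
        domains=ann.domains,
        expected_orientation=expected_orientation,
        n_duplicates=n_dup,
        config=config,
    )
    return pairs, truth


def _pair_frame(chrom1, pos1, strand1, chrom2, pos2, strand2) -> pd.DataFrame:
    n = len(pos1)
    return pd.DataFrame(
        {
            "chrom1": chrom1,
            "pos1": np.asarray(pos1, dtype=np.int64),
            "strand1": strand1,
            "mapq1": np.full(n, 60, dtype=np.int16),
            "nm1": np.zeros(n, dtype=np.int16),
            "chrom2": chrom2,
            "pos2": np.asarray(pos2, dtype=np.int64),
            "strand2": strand2,
            "mapq2": np.full(n, 60, dtype=np.int16),
            "nm2": np.zeros(n, dtype=np.int16),
        }
    )


def _rand_strands(rng, n: int) -> np.ndarray:
    return np.where(rng.random(n) < 0.5, "+", "-")


def _uniform_ligation(config: SimConfig, rng, chrom: str, n: int) -> pd.DataFrame:
    """Ligation pairs with uniform inter-end distance; accessibility bias is
    deliberately ignored (used for orientation calibration)."""
    L = config.chrom_sizes[chrom]
    lo, hi = config.uniform_range
    d = rng.integers(lo, hi + 1, size=n)
    p1 = rng.integers(0, L - d)
    return _pair_frame(chrom, p1, _rand_strands(rng, n), chrom, p1 + d, _rand_strands(rng, n))


def _ligation_pairs(
    config: SimConfig,
    rng,
    chrom: str,
    n_lig: int,
    b: np.ndarray,
    ann: Annotation,
    loops: pd.DataFrame,
    structured: bool,
) -> pd.DataFrame:
    bw = config.bin_width
    L = config.chrom_sizes[chrom]
    n = len(b)
    F = _decay_weights(config, n)
    e = config.domain_enrichment
    r = config.compartment_preference

    C = _autocorr(b)
    C = np.clip(C, 0, None)
    if structured:
        dom_id, type_code = _domain_codes(ann, chrom, bw, n)
        T = np.zeros(n)
        for t in (0, 1):
            xt = b * (type_code == t)
            T += _autocorr(xt)
        A = np.zeros(n)
        for d in np.unique(dom_id):
            xd = b * (dom_id == d)
            lo, hi = np.flatnonzero(dom_id == d)[[0, -1]]
            seg = xd[lo : hi + 1]
            A[: hi - lo + 1] += _autocorr(seg)
        T = np.clip(T, 0, None)
        A = np.clip(A, 0, None)
        C_eff = C + (e - r) * A + (r - 1.0) * T
    else:
        dom_id = type_code = None
        C_eff = C

    boost_by_k: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    lsub = loops[loops["chrom"] == chrom] if len(loops) else loops
    if len(lsub):
        kk = (lsub["bin2"] - lsub["bin1"]).to_numpy()
        for k in np.unique(kk):
            sel = kk == k
            idx = lsub["bin1"].to_numpy()[sel]
            mult = lsub["fold"].to_numpy()[sel]
            boost_by_k[int(k)] = (idx, mult)
            base_m = _pair_mult(dom_id, type_code, e, r, int(k), idx)
            C_eff[int(k)] += np.sum(b[idx] * b[idx + k] * base_m * (mult - 1.0))

    q = F * np.clip(C_eff, 0, None)
    q[q < 0] = 0
    counts = rng.multinomial(n_lig, q / q.sum())
    i_all = np.empty(n_lig, dtype=np.int64)
    j_all = np.empty(n_lig, dtype=np.int64)
    pos = 0
    for k in np.flatnonzero(counts):
        cnt = counts[k]
        w = b[: n - k] * b[k:] if k > 0 else b * b
        if structured:
            m = _offset_mult(dom_id, type_code, e, r, k)
            w = w * m
        if k in boost_by_k:
            idx, mult = boost_by_k[k]
            w = w.copy()
            w[idx] *= mult
        i = rng.choice(n - k if k > 0 else n, size=cnt, p=w / w.sum())
        i_all[pos : pos + cnt] = i
        j_all[pos : pos + cnt] = i + k
        pos += cnt
    widths1 = np.minimum((i_all + 1) * bw, L) - i_all * bw
    widths2 = np.minimum((j_all + 1) * bw, L) - j_all * bw
    p1 = i_all * bw + rng.integers(0, widths1)
    p2 = j_all * bw + rng.integers(0, widths2)
    return _pair_frame(
        chrom, p1, _rand_strands(rng, n_lig), chrom, p2, _rand_strands(rng, n_lig)
    )


def _offset_mult(dom_id, type_code, e: float, r: float, k: int):
    if dom_id is None:
        return 1.0
    if k == 0:
        return np.full(len(dom_id), e)
    same_dom = dom_id[:-k] == dom_id[k:]
    same_type = type_code[:-k] == type_code[k:]
    return np.where(same_dom, e, np.where(same_type, r, 1.0))


def _pair_mult(dom_id, type_code, e: float, r: float, k: int, idx: np.ndarray):
    if dom_id is None:
        return np.ones(len(idx))
    same_dom = dom_id[idx] == dom_id[idx + k]
    same_type = type_code[idx] == type_code[idx + k]
    return np.where(same_dom, e, np.where(same_type, r, 1.0))


def _nonligated_pairs(config: SimConfig, rng, chrom: str, n: int) -> pd.DataFrame:
    """Short unligated fragments: forward-reverse orientation, small distance."""
    L = config.chrom_sizes[chrom]
    lo, hi = config.nonligated_range
    d = rng.integers(lo, hi + 1, size=n)
    p1 = rng.integers(0, L - d)
    return _pair_frame(
        chrom, p1, np.full(n, "+"), chrom, p1 + d, np.full(n, "-")
    )


def _trans_pairs(config: SimConfig, rng, chroms, lengths, n: int) -> pd.DataFrame:
    p = lengths / lengths.sum()
    c1 = rng.choice(len(chroms), size=n, p=p)
    c2 = rng.choice(len(chroms), size=n, p=p)
    redo = c1 == c2
    guard = 0
    while redo.any():
        guard += 1
        if guard > 1000:
            raise RuntimeError("cannot draw trans pairs with a single chromosome")
        c2[redo] = rng.choice(len(chroms), size=int(redo.sum()), p=p)
        redo = c1 == c2
    p1 = (rng.random(n) * lengths[c1]).astype(np.int64)
    p2 = (rng.random(n) * lengths[c2]).astype(np.int64)
    return _pair_frame(
        np.asarray(chroms, dtype=object)[c1], p1, _rand_strands(rng, n),
        np.asarray(chroms, dtype=object)[c2], p2, _rand_strands(rng, n),
    )


def evaluate_recovery(
    calls: pd.DataFrame, truth: GroundTruth, binning
) -> dict[str, float]:
    """Sensitivity and false-discovery proportion of interaction calls
    against the planted loops (exact bin-pair matching on the binning the
    loops were planted on)."""
    if truth.loops is None or len(truth.loops) == 0:
        raise ValueError("ground truth contains no planted loops")
    planted = set()
    for _, row in truth.loops.iterrows():
        planted.add((row["chrom"], int(row["bin1"]), int(row["bin2"])))
    passed = calls[calls["passed"]] if "passed" in calls.columns else calls
    called = set()
    for _, row in passed.iterrows():
        offset = binning.chrom_slice(row["chrom1"]).start
        called.add((row["chrom1"], int(row["bin_id1"]) - offset, int(row["bin_id2"]) - offset))
    tp = len(called & planted)
    sensitivity = tp / len(planted)
    fdp = (len(called) - tp) / len(called) if called else 0.0
    return {
        "n_planted": len(planted),
        "n_called": len(called),
        "sensitivity": sensitivity,
        "fdp": fdp,
    }
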