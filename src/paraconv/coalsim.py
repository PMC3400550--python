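"""Coalescent simulator for a pair of recently duplicated paralogous loci.

The model is an event-driven structured coalescent for two loci (A, the
ancestral copy, and B, a young duplicate) sampled from one panmictic
population.  Going backwards in time:

* lineages carry ancestral-material segments and reside at one locus;
  two lineages at the same locus coalesce at rate 1 per pair (time in
  units of 2N generations internally; user-facing times are in 4N units);
* interlocus gene conversion moves a tract of a lineage's material to the
  other locus.  ``C`` is the population conversion rate 4Nc per site --
  the rate at which a given site is covered by a conversion tract -- so
  tract initiations occur at rate ``C/(2*lambda_tract)`` per site per
  lineage, with geometrically distributed tract lengths (mean
  ``lambda_tract``) truncated at the locus boundary.  A conversion splits
  the lineage: the covered material switches locus.  The per-site
  marginal process is then exactly a two-island model with migration
  rate ``C``, which gives an analytic check (:func:`two_lineage_oracle`);
* at the duplication time ``t_dup`` the young locus ceases to exist: all
  B material is relabelled A and conversion stops;
* the population underwent a stepwise expansion: for ``t > t_exp`` the
  ancestral size is ``N/f`` (coalescence rate multiplied by ``f``).

Mutations follow the infinite-sites model mapped onto ``L`` discrete
homologous sites (uniform placement, resampled on collision), calibrated
so that a constant-size single locus satisfies ``E[S] = theta*L*a_n``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimParams",
    "SimReplicate",
    "simulate",
    "two_lineage_oracle",
    "to_ms_text",
    "parse_ms_text",
]


@dataclass(frozen=True)
class SimParams:
    """Parameters of the duplicated-locus coalescent.

    Times (``t_dup``, ``t_exp``) are in units of 4N generations; ``theta``
    and ``C`` are per-site population rates (4Nu and 4Nc); ``growth_factor``
    is the ratio of current to ancestral population size (>= 1).
    """

    n_A: int
    n_B: int
    L: int
    theta: float
    C: float = 0.0
    lambda_tract: float = 1.0
    t_dup: float = 1.0
    growth_factor: float = 1.0
    t_exp: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_A < 0 or self.n_B < 0 or self.n_A + self.n_B < 2:
            raise ValueError("need n_A, n_B >= 0 and n_A + n_B >= 2")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if not (self.theta > 0) or not math.isfinite(self.theta):
            raise ValueError("theta must be positive and finite")
        if self.C < 0 or not math.isfinite(self.C):
            raise ValueError("C must be non-negative and finite")
        if self.C > 0 and self.lambda_tract < 1:
            raise ValueError("lambda_tract must be >= 1 when C > 0")
        if not (self.t_dup > 0):
            raise ValueError("t_dup must be positive")
        if self.growth_factor < 1:
            raise ValueError("growth_factor must be >= 1")
        if self.t_exp < 0:
            raise ValueError("t_exp must be >= 0")


@dataclass
class SimReplicate:
    """One simulated dataset: binary haplotypes at homologous sites.

    Rows 0..n_A-1 are locus-A samples, rows n_A..n_A+n_B-1 locus-B samples.
    ``positions`` are 1-based homologous site coordinates shared by the two
    loci (the homologous-site map is the identity); the ancestral state is 0.
    Columns are sites segregating in the full sample or fixed between loci.
    ``tmrca`` holds the grand-MRCA time of every site in 2N-generation units.
    """

    n_A: int
    n_B: int
    L: int
    positions: np.ndarray  # int, 1-based, ascending
    genotypes: np.ndarray  # (n_A + n_B) x len(positions), uint8
    tmrca: np.ndarray = field(repr=False, default=None)

    @property
    def haplotypes_A(self) -> np.ndarray:
        return self.genotypes[: self.n_A]

    @property
    def haplotypes_B(self) -> np.ndarray:
        return self.genotypes[self.n_A :]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimReplicate):
            return NotImplemented
        return (
            self.n_A == other.n_A
            and self.n_B == other.n_B
            and self.L == other.L
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.genotypes, other.genotypes)
        )


def two_lineage_oracle(C: float) -> tuple[float, float]:
    """Expected pair coalescence times under the conversion-as-migration limit.

    For a single site, constant size and an infinitely old duplication, the
    two lineages form a two-state Markov chain: in the same locus they
    coalesce at rate 1 and separate at rate C; in different loci they reunite
    at rate C.  Solving gives E[T_same] = 2 and E[T_diff] = 2 + 1/C (2N units).
    """
    if not (C > 0):
        raise ValueError("C must be positive")
    return 2.0, 2.0 + 1.0 / C


class _Lineage:
    __slots__ = ("deme", "segs", "mlen", "lo", "hi", "conv_rate")

    def __init__(self, deme: int, segs: list[tuple[int, int, int]]):
        self.deme = deme
        self.segs = segs  # sorted, non-overlapping (start, end, mask), end exclusive
        self._refresh()

    def _refresh(self) -> None:
        segs = self.segs
        self.mlen = sum(e - s for s, e, _ in segs)
        if segs:
            self.lo = segs[0][0]
            self.hi = segs[-1][1]  # exclusive
        else:
            self.lo = self.hi = 0
        self.conv_rate = 0.0


def _merge_segments(a, b, full_mask, t, tmrca):
    """Union of two segment lists; overlapping masks are OR-ed.

    Pieces reaching the full sample mask are the site MRCA: their time is
    recorded and they are dropped from further tracking.
    """
    out: list[tuple[int, int, int]] = []
    i = j = 0
    na, nb = len(a), len(b)
    ca = a[0] if na else None
    cb = b[0] if nb else None

    def emit(s, e, m):
        if m == full_mask:
            tmrca[s:e] = t
            return
        if out and out[-1][1] == s and out[-1][2] == m:
            out[-1] = (out[-1][0], e, m)
        else:
            out.append((s, e, m))

    while ca is not None or cb is not None:
        if cb is None or (ca is not None and ca[1] <= cb[0]):
            emit(*ca)
            i += 1
            ca = a[i] if i < na else None
            continue
        if ca is None or cb[1] <= ca[0]:
            emit(*cb)
            j += 1
            cb = b[j] if j < nb else None
            continue
        # overlap
        s1, e1, m1 = ca
        s2, e2, m2 = cb
        if s1 < s2:
            emit(s1, s2, m1)
            ca = (s2, e1, m1)
            continue
        if s2 < s1:
            emit(s2, s1, m2)
            cb = (s1, e2, m2)
            continue
        e = min(e1, e2)
        emit(s1, e, m1 | m2)
        ca = (e, e1, m1) if e < e1 else None
        if ca is None:
            i += 1
            ca = a[i] if i < na else None
        cb = (e, e2, m2) if e < e2 else None
        if cb is None:
            j += 1
            cb = b[j] if j < nb else None
    return out


def _split_tract(segs, ts, te):
    """Partition segments into parts inside / outside tract [ts, te)."""
    inside: list[tuple[int, int, int]] = []
    outside: list[tuple[int, int, int]] = []
    for s, e, m in segs:
        if e <= ts or s >= te:
            outside.append((s, e, m))
        else:
            if s < ts:
                outside.append((s, ts, m))
            inside.append((max(s, ts), min(e, te), m))
            if e > te:
                outside.append((te, e, m))
    # keep 'outside' sorted: pieces were appended in order except the te-tail
    outside.sort()
    return inside, outside


def simulate(params: SimParams, rng: np.random.Generator | None = None) -> SimReplicate:
    """Run one replicate of the duplicated-locus coalescent.

    A seeded ``rng`` (or ``params.seed``) makes the replicate deterministic.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_A, n_B, L = params.n_A, params.n_B, params.L
    n = n_A + n_B
    full_mask = (1 << n) - 1
    theta2 = params.theta / 2.0  # per site per lineage per 2N generations
    f = params.growth_factor
    t_exp = 2.0 * params.t_exp  # internal clock: 2N generations
    t_dup = 2.0 * params.t_dup
    C = params.C
    lam = params.lambda_tract
    conv_init = C / (2.0 * lam) if C > 0 else 0.0
    q = 1.0 - 1.0 / lam if lam > 1 else 0.0

    tmrca = np.full(L, np.nan)
    lineages: list[_Lineage] = []
    for i in range(n):
        lin = _Lineage(0 if i < n_A else 1, [(0, L, 1 << i)])
        lineages.append(lin)

    def conv_rate_of(lin: _Lineage) -> float:
        # rate of tract initiations whose tract intersects [lo, hi):
        # starts inside the span, plus the geometric tail mass to its left.
        if lin.mlen == 0:
            return 0.0
        extent = lin.hi - lin.lo
        if q > 0.0:
            tail = q * (1.0 - q ** lin.lo) / (1.0 - q)
        else:
            tail = 0.0
        return conv_init * (extent + tail)

    total_mlen = float(n * L)
    conv_total = 0.0
    if conv_init > 0.0:
        for lin in lineages:
            lin.conv_rate = conv_rate_of(lin)
            conv_total += lin.conv_rate

    mutations: list[tuple[int, int]] = []  # (site, mask)
    used_sites: set[int] = set()

    def place_mutations(dt: float) -> None:
        if total_mlen <= 0.0 or dt <= 0.0:
            return
        mean = theta2 * dt * total_mlen
        nmut = rng.poisson(mean) if mean > 0 else 0
        for _ in range(nmut):
            # lineage weighted by its material length
            u = rng.random() * total_mlen
            acc = 0.0
            lin = lineages[-1]
            for cand in lineages:
                acc += cand.mlen
                if u < acc:
                    lin = cand
                    break
            for _try in range(100):
                off = int(rng.random() * lin.mlen)
                site = -1
                mask = 0
                for s, e, m in lin.segs:
                    w = e - s
                    if off < w:
                        site = s + off
                        mask = m
                        break
                    off -= w
                if site >= 0 and site not in used_sites:
                    used_sites.add(site)
                    mutations.append((site, mask))
                    break

    t = 0.0
    dup_done = False
    kA = n_A
    kB = n_B
    while lineages:
        sizefac = 1.0 if t < t_exp else f
        rate_coal = 0.5 * (kA * (kA - 1) + kB * (kB - 1)) * sizefac
        rate_conv = conv_total if (not dup_done and conv_init > 0.0) else 0.0
        R = rate_coal + rate_conv
        if R <= 0.0:
            # isolated lineages in separate loci: nothing can happen until
            # the duplication merges the demes
            if dup_done:
                raise RuntimeError("coalescent stalled after duplication")
            place_mutations(t_dup - t)
            t = t_dup
            for lin in lineages:
                lin.deme = 0
            kA, kB = kA + kB, 0
            dup_done = True
            continue
        dt = rng.exponential(1.0 / R)
        t_next = t + dt
        if t < t_exp <= t_next:
            place_mutations(t_exp - t)
            t = t_exp
            continue
        if not dup_done and t_next >= t_dup:
            place_mutations(t_dup - t)
            t = t_dup
            for lin in lineages:
                lin.deme = 0
            kA, kB = kA + kB, 0
            dup_done = True
            continue
        place_mutations(dt)
        t = t_next
        if rng.random() * R < rate_coal:
            # coalescence: choose deme proportional to its pair count
            wA = 0.5 * kA * (kA - 1)
            wB = 0.5 * kB * (kB - 1)
            deme = 0 if rng.random() * (wA + wB) < wA else 1
            pool = [idx for idx, lin in enumerate(lineages) if lin.deme == deme]
            i1, i2 = rng.choice(len(pool), size=2, replace=False)
            a = lineages[pool[i1]]
            b = lineages[pool[i2]]
            merged = _merge_segments(a.segs, b.segs, full_mask, t, tmrca)
            total_mlen -= a.mlen + b.mlen
            conv_total -= a.conv_rate + b.conv_rate
            for idx in sorted((pool[i1], pool[i2]), reverse=True):
                last = lineages.pop()
                if idx < len(lineages):
                    lineages[idx] = last
            if deme == 0:
                kA -= 1
            else:
                kB -= 1
            if merged:
                lin = _Lineage(deme, merged)
                if conv_init > 0.0 and not dup_done:
                    lin.conv_rate = conv_rate_of(lin)
                total_mlen += lin.mlen
                conv_total += lin.conv_rate
                lineages.append(lin)
            else:
                if deme == 0:
                    kA -= 1
                else:
                    kB -= 1
        else:
            # gene conversion: pick lineage proportional to its hit rate
            u = rng.random() * conv_total
            acc = 0.0
            lin = lineages[-1]
            for cand in lineages:
                acc += cand.conv_rate
                if u < acc:
                    lin = cand
                    break
            extent = lin.hi - lin.lo
            tail = q * (1.0 - q ** lin.lo) / (1.0 - q) if q > 0.0 else 0.0
            if rng.random() * (extent + tail) < extent:
                ts = lin.lo + int(rng.random() * extent)
                length = rng.geometric(1.0 / lam)
            else:
                # start j sites left of the span with weight q**j (the tract
                # must be at least j+1 long to reach it); inverse-CDF draw of
                # j in 1..lo, then the residual length is geometric again
                r = rng.random()
                j = math.ceil(math.log(1.0 - r * (1.0 - q ** lin.lo)) / math.log(q))
                j = min(max(j, 1), lin.lo)
                ts = lin.lo - j
                length = j + rng.geometric(1.0 / lam)
            te = min(ts + length, L)
            inside, outside = _split_tract(lin.segs, ts, te)
            if not inside:
                continue
            conv_total -= lin.conv_rate
            if not outside:
                lin.deme = 1 - lin.deme
                if lin.deme == 0:
                    kA += 1
                    kB -= 1
                else:
                    kA -= 1
                    kB += 1
                lin.conv_rate = conv_rate_of(lin)
                conv_total += lin.conv_rate
            else:
                total_mlen -= lin.mlen
                lin.segs = outside
                lin._refresh()
                lin.conv_rate = conv_rate_of(lin)
                conv_total += lin.conv_rate
                total_mlen += lin.mlen
                new = _Lineage(1 - lin.deme, inside)
                new.conv_rate = conv_rate_of(new)
                conv_total += new.conv_rate
                total_mlen += new.mlen
                lineages.append(new)
                if new.deme == 0:
                    kA += 1
                else:
                    kB += 1

    # build output matrix from the recorded mutations
    keep = [(site, mask) for site, mask in mutations if 0 < mask < full_mask]
    keep.sort()
    positions = np.array([s + 1 for s, _ in keep], dtype=np.int64)
    geno = np.zeros((n, len(keep)), dtype=np.uint8)
    for col, (_, mask) in enumerate(keep):
        for row in range(n):
            if mask >> row & 1:
                geno[row, col] = 1
    return SimReplicate(n_A=n_A, n_B=n_B, L=L, positions=positions, genotypes=geno, tmrca=tmrca)


def to_ms_text(rep: SimReplicate) -> str:
    """Render a replicate as ms-style text, one ``//`` block per locus."""
    lines: list[str] = []
    pos = rep.positions
    for mat in (rep.haplotypes_A, rep.haplotypes_B):
        lines.append("//")
        lines.append(f"segsites: {len(pos)}")
        if len(pos):
            lines.append("positions: " + " ".join(f"{p / rep.L:.10f}" for p in pos))
            for row in mat:
                lines.append("".join("1" if x else "0" for x in row))
        lines.append("")
    return "\n".join(lines)


def parse_ms_text(text: str, L: int) -> SimReplicate:
    """Parse two-locus ms-style text produced by :func:`to_ms_text`."""
    blocks: list[tuple[np.ndarray, np.ndarray]] = []
    chunks = [c for c in text.split("//") if c.strip()]
    for chunk in chunks:
        lines = [ln for ln in chunk.strip().splitlines() if ln.strip()]
        seg = int(lines[0].split(":")[1])
        if seg == 0:
            blocks.append((np.array([], dtype=np.int64), np.zeros((0, 0), dtype=np.uint8)))
            continue
        pos = np.array(
            [int(round(float(p) * L)) for p in lines[1].split(":")[1].split()],
            dtype=np.int64,
        )
        rows = [[1 if ch == "1" else 0 for ch in ln.strip()] for ln in lines[2:]]
        blocks.append((pos, np.array(rows, dtype=np.uint8)))
    if len(blocks) != 2:
        raise ValueError("expected exactly two locus blocks")
    (pos_a, mat_a), (pos_b, mat_b) = blocks
    if len(pos_a) and len(pos_b) and not np.array_equal(pos_a, pos_b):
        raise ValueError("locus blocks disagree on homologous positions")
    pos = pos_a if len(pos_a) else pos_b
    n_A = mat_a.shape[0]
    n_B = mat_b.shape[0]
    if mat_a.size == 0 and mat_b.size == 0:
        geno = np.zeros((n_A + n_B, 0), dtype=np.uint8)
    else:
        geno = np.vstack([m for m in (mat_a, mat_b) if m.size]) if (n_A and n_B) else (mat_a if n_A else mat_b)
    return SimReplicate(n_A=n_A, n_B=n_B, L=L, positions=pos, genotypes=geno)
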