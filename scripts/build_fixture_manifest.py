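"""Build the brute-force expected-output manifest for the worked fixture.

Run once from the repository root:

    python scripts/build_fixture_manifest.py

Every statistic here is recomputed by naive enumeration (explicit Python
loops, no calls into the analysis functions under test) so that the manifest
in tests/fixtures/worked_manifest.json is an independent oracle for the
allelic pipeline: filter funnel counts, escapee set, reactivation
timepoints, per-cluster reactivated fractions, relative differential peak
values and promoter accessibility sums.
"""

import json
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from xistruct.simulate import make_worked_fixture  # noqa: E402

CUTOFF = 0.14
BIALLELIC = (0.4, 0.6)
PCT = 0.25


def quantile_type7(values, q):
    """Linear-interpolation quantile, computed from first principles."""
    xs = sorted(values)
    h = (len(xs) - 1) * q
    lo = int(h)
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def main() -> None:
    fx = make_worked_fixture()
    genes = fx["genes"]
    timepoints = list(fx["config"].timepoints)
    reference = timepoints[0]
    endpoints = timepoints[-2:]

    # --- filter funnel ---------------------------------------------------
    rows = genes.to_dict("records")
    stage1 = [r for r in rows if r["snp_informative"]]
    thr = quantile_type7([r[f"cas_{reference}"] for r in stage1], PCT)
    stage2 = [r for r in stage1 if r[f"cas_{reference}"] >= thr]
    funnel = {"input": len(rows), "snp_informative": len(stage1), "expressed": len(stage2)}

    # --- ratios and calls -------------------------------------------------
    def ratio(r, t):
        m, c = r[f"mus_{t}"], r[f"cas_{t}"]
        return None if m + c == 0 else m / (m + c)

    escapees = sorted(r["gene"] for r in stage2
                      if (ratio(r, reference) or 0) > CUTOFF)

    def is_biallelic(r):
        for t in endpoints:
            x = ratio(r, t)
            if x is None or not (BIALLELIC[0] < x < BIALLELIC[1]):
                return False
        return True

    biallelic = [r for r in stage2 if is_biallelic(r)]
    reactivation = {}
    for r in biallelic:
        for t in timepoints:
            x = ratio(r, t)
            if x is not None and x > CUTOFF:
                reactivation[r["gene"]] = t
                break

    # --- per-cluster reactivated fractions --------------------------------
    clustering = fx["clustering"]
    bins = fx["bins"]
    res = bins.resolution
    n_bins = bins.n_bins

    def cluster_of(tss):
        b = min(tss // res, n_bins - 1)
        c = int(clustering.cluster_id[b])
        return None if c == -1 else c

    frac = {}
    for c in range(1, clustering.k + 1):
        members = [r for r in biallelic if cluster_of(r["tss"]) == c]
        if not members:
            continue
        frac[str(c)] = {
            t: sum(1 for r in members if (ratio(r, t) or 0) > CUTOFF) / len(members)
            for t in timepoints
        }

    # --- relative differential peaks --------------------------------------
    peak_sets = fx["peak_sets"]
    base = peak_sets[reference][["start", "end"]].to_records(index=False)

    def overlaps_baseline(s, e):
        return any(min(e, be) > max(s, bs) for bs, be in base)

    diff_counts = {}
    for t in timepoints:
        counts = {c: 0 for c in range(1, clustering.k + 1)}
        for s, e in peak_sets[t][["start", "end"]].to_records(index=False):
            if overlaps_baseline(s, e):
                continue
            c = cluster_of((s + e) // 2)
            if c is not None:
                counts[c] += 1
        diff_counts[t] = counts
    end_t = timepoints[-1]
    rel_peaks = {}
    for c in range(1, clustering.k + 1):
        denom = diff_counts[end_t][c]
        rel_peaks[str(c)] = {
            t: (diff_counts[t][c] / denom if denom else None) for t in timepoints
        }

    # --- promoter accessibility -------------------------------------------
    signal = fx["signal"][["start", "end", "value"]].to_records(index=False)
    promoter = {}
    for r in stage2:
        lo, hi = r["tss"] - 2000, r["tss"] + 2000
        total = 0.0
        for s, e, v in signal:
            ov = min(e, hi) - max(s, lo)
            if ov > 0:
                total += v * ov
        promoter[r["gene"]] = total

    manifest = {
        "seed": fx["config"].seed,
        "funnel": funnel,
        "escapees": escapees,
        "biallelic_genes": sorted(r["gene"] for r in biallelic),
        "reactivation_time": reactivation,
        "fraction_reactivated": frac,
        "relative_differential_peaks": rel_peaks,
        "promoter_accessibility": promoter,
    }
    out = pathlib.Path(__file__).resolve().parents[1] / "tests" / "fixtures" / "worked_manifest.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    print(f"wrote {out} ({out.stat().st_size} bytes)")


if __name__ == "__main__":
    main()
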