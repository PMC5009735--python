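"""k-mer enrichment z-scores around crosslink sites.

For every crosslink assigned to one feature class (3'UTR or ncRNA; antisense
crosslinks are excluded by assignment), a transcript-strand-oriented sequence
window (default offsets -50..+50) is extracted around the site, clipped at the
boundaries of the containing feature interval. The observed score of a k-mer
is the fraction of windows containing it at least once. Each of ``n_random``
randomizations draws the same number of positions uniformly from the same
feature class's annotated intervals and is scored identically; the z-score
standardizes the observed score by the randomization mean and sd. k-mers are
reported in the RNA alphabet (T transliterated to U).
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation
from .features import annotate_crosslinks
from .synthetic import reverse_complement

Z_CAP = 10.0


def _window_sequence(
    seq: str, pos: int, strand: str, window: tuple[int, int], bounds: tuple[int, int]
) -> str:
    """Window around ``pos`` in transcript orientation, clipped to ``bounds``."""
    w0, w1 = window
    if strand == "+":
        lo = max(pos + w0, bounds[0])
        hi = min(pos + w1 + 1, bounds[1])
        return seq[lo:hi] if hi > lo else ""
    lo = max(pos - w1, bounds[0])
    hi = min(pos - w0 + 1, bounds[1])
    return reverse_complement(seq[lo:hi]) if hi > lo else ""


def _containing_feature(annotation, chrom, pos, strand, feature_class):
    for gene in annotation.genes_overlapping(chrom, pos):
        if gene.strand != strand:
            continue
        for t in gene.transcripts:
            for f in t.features:
                if f.cls == feature_class and f.start <= pos < f.end:
                    return f
    return None


def _score_windows(windows: list[str], k: int) -> dict[str, float]:
    """Fraction of windows containing each k-mer at least once."""
    n = len(windows)
    hits: dict[str, int] = {}
    for w in windows:
        present = {w[i : i + k] for i in range(len(w) - k + 1)}
        for kmer in present:
            hits[kmer] = hits.get(kmer, 0) + 1
    return {kmer: c / n for kmer, c in hits.items()} if n else {}


def kmer_scores(
    table: pd.DataFrame,
    annotation: GenomeAnnotation,
    genome: list,
    feature_class: str = "3UTR",
    k: int = 5,
    window: tuple[int, int] = (-50, 50),
    n_random: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed vs randomized k-mer window scores for all 4^k k-mers.

    Returns a frame with columns kmer (RNA alphabet), observed, random_mean,
    random_sd, z, sorted by z descending with lexicographic tie-break. When
    fewer than 10 crosslinks fall in the class the result is flagged
    low-confidence (``df.attrs["low_confidence"]``).
    """
    if feature_class not in ("3UTR", "ncRNA"):
        raise ValueError("feature_class must be '3UTR' or 'ncRNA'")
    rng = np.random.default_rng(seed)
    seqs = {rec.id: rec.sequence for rec in genome}

    ann = annotate_crosslinks(table, annotation)
    sites = ann[ann["feature"] == feature_class]
    low_confidence = len(sites) < 10
    if low_confidence:
        warnings.warn(
            f"only {len(sites)} crosslinks in class {feature_class}; "
            "k-mer scores are low-confidence",
            stacklevel=2,
        )

    windows = []
    for chrom, pos, strand in sites[["chrom", "position", "strand"]].itertuples(
        index=False, name=None
    ):
        f = _containing_feature(annotation, chrom, int(pos), strand, feature_class)
        if f is None:
            continue
        w = _window_sequence(seqs[chrom], int(pos), strand, window, (f.start, f.end))
        if len(w) >= k:
            windows.append(w)
    observed = _score_windows(windows, k)

    # randomized positions from the same feature class, uniform over interval nt
    feats = annotation.features_of_class(feature_class)
    starts = np.array([f.start for _, f in feats])
    lens = np.array([len(f) for _, f in feats])
    strands = [g.strand for g, _ in feats]
    chroms = [g.chrom for g, _ in feats]
    weights = lens / lens.sum() if len(feats) else None

    sum_scores: dict[str, float] = {}
    sumsq_scores: dict[str, float] = {}
    for _ in range(n_random):
        rnd_windows = []
        if weights is not None and windows:
            picks = rng.choice(len(feats), size=len(windows), p=weights)
            offs = rng.integers(0, lens[picks])
            for i, off in zip(picks, offs):
                f = feats[i][1]
                pos = int(starts[i] + off)
                w = _window_sequence(
                    seqs[chroms[i]], pos, strands[i], window, (f.start, f.end)
                )
                if len(w) >= k:
                    rnd_windows.append(w)
        for kmer, s in _score_windows(rnd_windows, k).items():
            sum_scores[kmer] = sum_scores.get(kmer, 0.0) + s
            sumsq_scores[kmer] = sumsq_scores.get(kmer, 0.0) + s * s

    all_kmers = ["".join(t) for t in itertools.product("ACGT", repeat=k)]
    recs = []
    for kmer in all_kmers:
        obs = observed.get(kmer, 0.0)
        mean = sum_scores.get(kmer, 0.0) / n_random if n_random else 0.0
        var = max(sumsq_scores.get(kmer, 0.0) / n_random - mean * mean, 0.0) if n_random else 0.0
        sd = float(np.sqrt(var))
        if sd > 0:
            z = float((obs - mean) / sd)
        else:
            # degenerate randomization: bounded so the table stays sortable
            z = 0.0 if obs == mean else float(np.sign(obs - mean) * Z_CAP)
        recs.append({
            "kmer": kmer.replace("T", "U"),
            "observed": obs,
            "random_mean": mean,
            "random_sd": sd,
            "z": z,
        })
    df = pd.DataFrame(recs).sort_values(["z", "kmer"], ascending=[False, True]).reset_index(drop=True)
    df.attrs["low_confidence"] = low_confidence
    df.attrs["n_windows"] = len(windows)
    return df


def top_kmers(scores: pd.DataFrame, n: int) -> list[str]:
    """Top-n k-mers by z, ties broken lexicographically."""
    ordered = scores.sort_values(["z", "kmer"], ascending=[False, True])
    return list(ordered["kmer"].head(n))
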