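"""Normalized coverage profiles across scaled gene bodies with flanks.

Each gene body is rescaled to a fixed number of bins; flanks use
fixed-width bins. Bin value is the mean per-bp coverage inside the bin (so
genes of unequal length are comparable), averaged across genes and
converted to reads-per-million with the sample's library size.
Minus-strand genes are reversed so bin 0 is always 5'-most.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import CoverageTrack, GeneModel


@dataclass
class MetageneProfile:
    upstream: np.ndarray  # flank_bins RPM values, 5' flank
    body: np.ndarray  # body_bins RPM values
    downstream: np.ndarray  # flank_bins RPM values, 3' flank
    flank: int
    n_genes: int
    n_skipped: int

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.upstream, self.body, self.downstream])


def _gene_bins(g: GeneModel, body_bins: int, flank: int, flank_bins: int):
    """Bin edges along the genome for one gene, 5'->3'; returns (starts,
    ends) arrays of length flank_bins + body_bins + flank_bins."""
    body_edges = np.floor(g.start + (g.end - g.start) * np.arange(body_bins + 1) / body_bins
                          ).astype(np.int64)
    if flank_bins > 0 and flank > 0:
        up_edges = np.floor(g.start - flank + flank * np.arange(flank_bins + 1) / flank_bins
                            ).astype(np.int64)
        dn_edges = np.floor(g.end + flank * np.arange(flank_bins + 1) / flank_bins
                            ).astype(np.int64)
        edges_start = np.concatenate([up_edges[:-1], body_edges[:-1], dn_edges[:-1]])
        edges_end = np.concatenate([up_edges[1:], body_edges[1:], dn_edges[1:]])
    else:
        edges_start, edges_end = body_edges[:-1], body_edges[1:]
    if g.strand == "-":
        edges_start, edges_end = edges_start[::-1], edges_end[::-1]
    return edges_start, edges_end


def metagene_profile(track: CoverageTrack, genes: Sequence[GeneModel],
                     body_bins: int = 100, flank: int = 2000,
                     flank_bins: int = 20, library_size: float = 1e6) -> MetageneProfile:
    """Mean per-bin coverage across genes, in RPM.

    Genes shorter than ``body_bins`` bp are skipped (their bins would be
    sub-bp) and counted in ``n_skipped``. Genes whose upstream flank would
    cross the chromosome origin are also skipped.
    """
    if not genes:
        raise ValueError("genes must be non-empty")
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    n_bins = 2 * flank_bins + body_bins
    total = np.zeros(n_bins)
    used = skipped = 0
    for g in genes:
        if g.end - g.start < body_bins or g.start - flank < 0:
            skipped += 1
            continue
        s, e = _gene_bins(g, body_bins, flank, flank_bins)
        total += track.mean(g.chrom, s, e)
        used += 1
    if used == 0:
        raise ValueError("all genes skipped (too short or too close to origin)")
    mean_cov = total / used
    rpm_vals = mean_cov / (library_size / 1e6)
    fb = flank_bins
    return MetageneProfile(rpm_vals[:fb], rpm_vals[fb:fb + body_bins],
                           rpm_vals[fb + body_bins:], flank, used, skipped)


def compare_profiles(profile_a: MetageneProfile, profile_b: MetageneProfile):
    """Per-bin differences (A - B) and the fraction of body bins where
    group A is strictly lower than group B."""
    if len(profile_a.values) != len(profile_b.values) or \
            len(profile_a.body) != len(profile_b.body):
        raise ValueError("profiles have mismatched binning")
    diff = profile_a.values - profile_b.values
    frac_lower = float(np.mean(profile_a.body < profile_b.body))
    return diff, frac_lower
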