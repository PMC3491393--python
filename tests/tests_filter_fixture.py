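"""Hand-built 20-site variant table with planted filter violations.

14 clean sites pass every confidence criterion; six sites each violate
exactly one filter.  The expected survivors are enumerated by hand so
the filter can be checked against an independent count.
"""

import numpy as np

from tfbsload.variation import HET, MISSING, VariantSite

N_STRAINS = 162


def _site(pos, eps=0.01, cov=(10.0, 8.0), med=12.0, n_alt=40,
          n_missing=0, n_het=0):
    calls = np.zeros(N_STRAINS, dtype=np.int8)
    calls[:n_alt] = 1
    if n_missing:
        calls[n_alt:n_alt + n_missing] = MISSING
    if n_het:
        calls[n_alt + n_missing:n_alt + n_missing + n_het] = HET
    return VariantSite("chr2L", pos, "A", ("T",), calls, ploidy=1,
                       eps=eps, allele_coverage=cov,
                       median_coverage=med)


def build_planted_sites():
    """Returns (sites, positions expected to survive filtering)."""
    clean_positions = list(range(100, 114))
    sites = [_site(pos) for pos in clean_positions]
    sites += [
        _site(300, eps=0.05),            # per-SNP error too high
        _site(301, cov=(10.0, 2.0)),     # alt allele coverage < 3
        _site(302, med=30.0),            # median coverage > 20
        _site(303, n_het=20),            # > 5% heterozygous calls
        _site(304, n_missing=70),        # < 100 homozygous strains
        # major allele p * eps = (122/162) * 0.015 > 0.01 -> pruned
        _site(305, eps=0.015),
    ]
    return sites, clean_positions
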