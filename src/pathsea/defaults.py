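"""Package-wide analysis defaults.

These are the parameter values used throughout the pipeline unless a caller
overrides them: mass and retention-time tolerances for adduct grouping and
database matching, the permutation count and FDR threshold for
signal-to-noise filtering, the number of 1D-SOM prototypes, the
ratio threshold for profile labeling, and the size cut-off above which
unspecific "global" pathways are excluded from enrichment testing.
"""

MASS_TOL = 0.01  #: Da — adduct grouping and compound mass matching
RT_TOL = 0.05  #: minutes — co-elution window for adduct grouping
PERMUTATIONS = 1000  #: label permutations for the SNR FDR estimate
ALPHA = 0.05  #: FDR threshold for feature filtering
SOM_K = 30  #: number of 1D-SOM prototypes/clusters
LABEL_RATIO = 2.0  #: SNR ratio above which features receive a profile label
MAX_PATHWAY_ENTRIES = 500  #: pathways with more entries are excluded
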