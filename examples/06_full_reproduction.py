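"""The whole analysis in one call.

reproduce_paper() chains fixture loading, exact search, condensation,
fit statistics, jackknife resampling and clade diagnosis, and returns
a report whose every number is a function of (fixture, seed, config).
Replicates are reduced here for speed; pass replicates=2000 for the
full resampling.
"""

from fitchclade import reproduce_paper

report = reproduce_paper(seed=1, replicates=200)
print(report.summary())

# report.write("out/") drops summary.txt, Newick trees (with and
# without support annotations), and TSVs of step accounting, branch
# changes and split support.
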