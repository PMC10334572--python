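"""Generate a synthetic egg survey and summarize it per metal and season.

The survey emulates a two-season market basket: 21 brands x 2 replicate
eggs per season, As and Hg measured by ICP-MS in µg/kg wet weight, values
below the 0.0003 µg/kg detection limit substituted with zero.
"""

from eggrisk import SyntheticSurveyConfig, generate_survey, summaries_frame, summarize

records, truth = generate_survey(SyntheticSurveyConfig(seed=7))
print(f"{len(records)} measurements ({truth['n_per_cell']} per metal x season)\n")

rows = summarize(records, ("metal", "season")) + summarize(records, ("metal",))
print(summaries_frame(rows).to_string(index=False))
print(
    "\nEach row: sample size, range, arithmetic mean and its standard error"
    " (µg/kg wet weight); 'pooled' merges both seasons."
)
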