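#!/usr/bin/env python
"""Generate the synthetic multi-survey scenario.

Produces record-level data for 17 RLMS-like annual rounds (1996-2016,
2011-2012 excluded) plus five independent cross-sections with differing
years, age ranges, sample sizes and smoking-question variants, and writes
them to results/data/records.csv.
"""

import argparse

from smoketrends.pipeline_io import write_survey_csv
from smoketrends.survey_synth import (PrevalenceSurface, cross_sectional_designs,
                                      generate_scenario, rlms_designs)

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
args = ap.parse_args()

surface = PrevalenceSurface.default()
designs = rlms_designs() + cross_sectional_designs()
records = generate_scenario(designs, surface, args.seed)
write_survey_csv(records, "results/data/records.csv")

by = records.groupby("survey").agg(year=("year", "first"), n=("survey", "size"),
                                   age_min=("age", "min"), age_max=("age", "max"))
print(f"generated {len(records)} records across {len(designs)} surveys "
      f"({by.year.min()}-{by.year.max()})")
print(by.to_string())
print("wrote results/data/records.csv")
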