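"""Mortality accounting: how large is the decline, and who gained?

Computes expected final-year deaths under base-year rates, total deaths
prevented or postponed (DPPs), and age-standardised rates with absolute and
relative reductions, overall and per sex and socioeconomic quintile.
"""

import argparse
from pathlib import Path

import impactsec as im
from impactsec.io import read_inputs

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--inputs", type=Path, default=Path("results/inputs"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

inputs = read_inputs(args.inputs)
summary = im.mortality_summary(inputs["mortality"])
args.out.mkdir(parents=True, exist_ok=True)
summary.to_csv(args.out / "mortality_summary.csv")

t = summary.loc["total"]
print(f"total DPPs: {t['dpp']:.0f} (expected {t['expected_final']:.0f}, "
      f"observed {t['deaths_final']:.0f})")
print(f"age-standardised rate fell {t['rate_base']:.0f} -> {t['rate_final']:.0f} "
      f"per 100,000 ({t['rel_reduction']:.1f}% relative reduction)")
worst = summary.loc["secq_5"]
best = summary.loc["secq_1"]
print(f"absolute reduction largest in the most deprived quintile "
      f"({worst['abs_reduction']:.0f} vs {best['abs_reduction']:.0f} per 100,000); "
      f"relative reduction largest in the most affluent "
      f"({best['rel_reduction']:.1f}% vs {worst['rel_reduction']:.1f}%)")
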