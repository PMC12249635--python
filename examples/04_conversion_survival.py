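"""Time-to-conversion analysis of a module score in the MCI cohort.

Splits mild-cognitive-impairment individuals at the median score,
compares conversion curves with Kaplan-Meier + log-rank, and fits a Cox
proportional-hazards model (score per SD, adjusted for age, sex and
education) whose hazard ratio should recover the generative 1.3.
"""

import numpy as np
import pandas as pd

from mprsnet.clinical import cox_ph, km_logrank, median_split
from mprsnet.synthetic import SimulationConfig, generate_phenotypes

cfg = SimulationConfig(seed=42, n_individuals=3000)
rng = np.random.default_rng(0)
x = rng.standard_normal(cfg.n_individuals)  # standardized module score
pheno, truth = generate_phenotypes(x, cfg)

mci = pheno[pheno["conv_months"].notna()]
score = pd.Series((x - x.mean()) / x.std(ddof=1), index=pheno.index).loc[mci.index]
groups = median_split(score)
print(f"MCI cohort: {len(mci)} individuals, "
      f"{int(mci['conv_event'].sum())} converted, "
      f"{(groups == 'high').sum()} high-risk / {(groups == 'low').sum()} low-risk")

km = km_logrank(mci["conv_months"], mci["conv_event"].astype(int), groups)
print(f"log-rank chi2 = {km.logrank_chi2:.1f}, p = {km.logrank_p:.2e}")

cov = pd.DataFrame({
    "mprs_z": score.to_numpy(),
    "age": mci["age"].to_numpy(),
    "sex": (mci["sex"] == "M").astype(float).to_numpy(),
    "education": mci["education"].to_numpy(),
})
cox = cox_ph(mci["conv_months"], mci["conv_event"].astype(int), cov)
row = cox.cox.set_index("covariate").loc["mprs_z"]
print(f"Cox HR per SD = {row['hr']:.3f} "
      f"[{row['ci_low']:.3f}, {row['ci_high']:.3f}], p = {row['p']:.2e} "
      f"(generative HR {truth['true_hr_per_sd']:.2f})")
# A HR of ~1.3 per SD means each standard deviation of module risk score
# multiplies the monthly conversion hazard by ~1.3, independent of the
# demographic covariates.
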