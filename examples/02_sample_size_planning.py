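"""Plan the sample size for a paired A-Not A study.

Starting from a pilot guess expressed as an odds ratio and a proportion of
discordant pairs, computes the minimum effective sample size N (response
pairs) under all three methods, then prints the standard planning grid.
"""

from anota import DesignSpec, miettinen_n, bu_n, exact_n, sample_size_grid

spec = DesignSpec.from_or_pd(OR=5, p_D=0.2, alpha=0.05, target_power=0.8)
print(f"design: p_b = {spec.p_b:.4f}, p_c = {spec.p_c:.4f} "
      f"(OR = 5, p_D = 0.2), one-tailed alpha = .05, power = .8")
print(f"  Miettinen closed form:        N = {miettinen_n(spec)}")
print(f"  Bennett-Underwood inversion:  N = {bu_n(spec)}")
print(f"  unconditional exact:          N = {exact_n(spec)}")
print("The exact method is the most conservative; the closed form gives a "
      "quick lower anchor. Plan for the largest N to be safe.")

print("\nplanning grid (Miettinen N per OR x p_D cell):")
df = sample_size_grid(methods=("miettinen",))
print(df.pivot(index="p_D", columns="OR", values="N_miettinen"))
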