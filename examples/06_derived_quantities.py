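"""Derived quantities implied by the published benchmark estimates.

The post-estimation arithmetic a reader applies to the coefficient tables:
percent effects on the birth interval, the mortality-minimizing interval
length, the maternal age minimizing first-born mortality, heterogeneity
variance shares, and the heterogeneity correlation structure.
"""
import replsim

params = replsim.comparison_area_params()
print(replsim.derived_report(params))
print("Negative correlation between the mortality and fertility "
      "heterogeneity terms means unobserved factors raising death risk go "
      "with lower fertility; the large negative interval-fertility "
      "correlation says mothers who want many children also space briefly.")
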