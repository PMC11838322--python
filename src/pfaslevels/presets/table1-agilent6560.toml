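# Recommended default tolerances for an Agilent 6560-class drift-tube
# LC-IMS-QTOF platform running PFAS non-targeted analysis.

[mz]
ppm = 10.0

[isotope]
reldev_max = 0.10     # absolute deviation of base-peak-normalized abundances
exempt_area = 5000.0  # features below this area with no M+1/M+2 are exempt

[ccs]
reference_standard = 0.2
library = 2.0
predicted = 5.0       # homologous-series trendline predictions

[rt]
reference_standard = 0.5
library = 0.5
predicted = "monotonic"  # RT must increase with m/z within a series

[ms2]
reference_standard = 0.9
library_similar = 0.8
library_other = 0.7
fragment_tol = 0.01

[support]
multiplier = 2.0

[platform]
rp = 60.0  # single-peak resolving power, drift-tube IMS
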