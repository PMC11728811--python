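# Packaged default scenario: six organic paint solvents in steel
# shipbuilding, probabilistic inhalation risk.
#
# Concentrations: per-chemical lognormal, moment-matched to the published
# arithmetic mean/SD of the 2018 workplace-monitoring samples (ppm).
# Worker factors: daily exposure time ET (logistic, hours/day), exposure
# duration ED (exponential, years), exposure frequency EF (lognormal,
# days/year), averaging time AT fixed at 69,408 days.
iterations: 10000
seed: 12345
at_days: 69408
molar_volume_l_per_mol: 24.45
chemicals:
  - name: xylene
    mw: 106.17
    rfc: {nervous: 0.1}
    rfd: {other: 0.2}
    count: 952
    concentration: {family: lognormal, mean_ppm: 19.66, sd_ppm: 51.24}
  - name: n-butanol
    mw: 74.12
    rfd: {nervous: 0.1}
    count: 449
    concentration: {family: lognormal, mean_ppm: 12.84, sd_ppm: 29.37}
  - name: ethylbenzene
    mw: 106.17
    rfc: {developmental: 1.0}
    rfd: {hepatic: 0.1, urinary: 0.1}
    count: 868
    concentration: {family: lognormal, mean_ppm: 9.44, sd_ppm: 25.26}
  - name: isobutyl alcohol
    mw: 74.12
    rfd: {nervous: 0.3}
    count: 172
    concentration: {family: lognormal, mean_ppm: 4.50, sd_ppm: 6.62}
  - name: toluene
    mw: 92.14
    rfc: {nervous: 5.0}
    rfd: {urinary: 0.08}
    count: 427
    concentration: {family: lognormal, mean_ppm: 2.50, sd_ppm: 5.40}
  - name: mibk
    mw: 100.16
    rfc: {developmental: 3.0}
    count: 290
    concentration: {family: lognormal, mean_ppm: 2.56, sd_ppm: 4.07}
factors:
  daily_exposure_time: {family: logistic, mean: 8.0, sd: 1.11}      # hours/day
  exposure_duration: {family: exponential, mean: 11.0, sd: 8.69}    # years
  exposure_frequency: {family: lognormal, mean: 268.0, sd: 20.92}   # days/year
groupings:
  nervous: [xylene, n-butanol, isobutyl alcohol, toluene]
  developmental: [mibk, ethylbenzene]
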