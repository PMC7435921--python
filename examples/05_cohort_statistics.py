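"""Run the full pipeline on a simulated cohort and print the population table.

The pipeline simulates 22 patients, extracts spectral parameters and
entropy/MI per analysis window, and summarizes the cohort as mean ± SD per
channel with paired LV-vs-RV t-tests.  The emulated population reproduces
the qualitative inter-ventricular pattern: higher dominant frequency in the
LV, higher organization in the RV.
"""

from vfegm import RunConfig, SimulateConfig, run_pipeline

result = run_pipeline(
    RunConfig(output_dir="cohort_run", simulate=SimulateConfig(n_patients=22), seed=7)
)
print(result.cohort_txt.read_text())
print(f"CSV artifacts: {result.spectral_csv}, {result.info_csv}, {result.cohort_csv}")
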