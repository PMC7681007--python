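# Worked-example manifest: H3K27me3 native ChIP (DMSO-treated HCT116).
#
# The IP block carries the published bench numbers for this experiment:
# 37,298,373 mapped fragments from sequencing 20 fmol of an 856 fmol
# library (F_L = 20/856 = 0.02336), 11 PCR cycles, and 10 of 24.2 ng of
# IP material carried into library prep (F = 0.413). The bead-capture
# yield rho was not reported, so the no-loss limit rho = 1 is used here;
# with rho = 1 the scaled total-read estimate differs from the published
# 226 million figure, which implies an unpublished rho.
#
# The input block and the reaction volumes were not reported for this
# experiment; the values below are placeholders so the file parses and
# the factor report can be demonstrated. Replace them with your own
# measurements before interpreting alpha.
ip:
  mapped_reads: 37298373
  library_sequenced: 20      # fmol
  library_total: 856         # fmol
  pcr_cycles: 11
  ip_mass_total: 24.2        # ng
  mass_into_library: 10      # ng
  bead_capture_yield: 1.0
input:
  mapped_reads: 37298373     # placeholder
  library_sequenced: 20      # placeholder, fmol
  library_total: 856         # placeholder, fmol
  pcr_cycles: 11             # placeholder
  ip_mass_total: 24.2        # placeholder, ng
  mass_into_library: 10      # placeholder, ng
  bead_capture_yield: 1.0
volumes:
  total_volume: 110          # ul, placeholder
  input_aliquot: 10          # ul, placeholder
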