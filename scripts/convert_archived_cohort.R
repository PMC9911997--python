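#!/usr/bin/env Rscript
# Convert the archived study cohort (CRAN package TH.data, dataset
# `blood_loss`, available from TH.data >= 1.1-2) into the cohort CSV
# schema this package reads.  Run with network access / a local TH.data:
#
#   Rscript scripts/convert_archived_cohort.R data/external/blood_loss.csv
#
# Column names below follow the dataset's documentation (?TH.data::blood_loss);
# verify them against the installed TH.data version before use.

args <- commandArgs(trailingOnly = TRUE)
out <- if (length(args) >= 1) args[[1]] else "data/external/blood_loss.csv"

if (!requireNamespace("TH.data", quietly = TRUE))
  stop("TH.data is not installed; install.packages('TH.data') (>= 1.1-2)")

env <- new.env()
ok <- tryCatch({
  data("blood_loss", package = "TH.data", envir = env)
  TRUE
}, warning = function(w) FALSE, error = function(e) FALSE)
if (!ok || is.null(env$blood_loss))
  stop("this TH.data version does not ship the 'blood_loss' dataset; ",
       "need TH.data >= 1.1-2 from CRAN")

bl <- env$blood_loss

pick <- function(df, patterns) {
  for (p in patterns) {
    hit <- grep(p, names(df), ignore.case = TRUE, value = TRUE)
    if (length(hit) >= 1) return(df[[hit[[1]]]])
  }
  stop("no column matching: ", paste(patterns, collapse = " | "))
}

mode_raw <- tolower(as.character(pick(bl, c("mode", "delivery"))))
mode <- ifelse(grepl("unplan|second|emerg", mode_raw), "unplanned_cs",
        ifelse(grepl("cesar|caesar|section|elect|prim", mode_raw), "elective_cs",
               "vaginal"))

cohort <- data.frame(
  mbl            = pick(bl, c("^MBL$", "blood.?loss")),
  delivery_mode  = mode,
  platelets_pre  = pick(bl, c("PLT.*prae", "prae.*PLT", "platelet.*pre", "^PLT$")),
  hemoglobin_pre = pick(bl, c("H(b|GB).*prae", "prae.*H(b|GB)", "h(a)?emoglobin")),
  fibrinogen_pre = pick(bl, c("F\\.?I\\.?prae", "fib")),
  fii_pre        = pick(bl, c("F\\.?II\\.?prae", "F\\.?II$")),
  fxiii_pre      = pick(bl, c("F\\.?XIII\\.?prae", "F\\.?XIII$")),
  platelets_post = pick(bl, c("PLT.*post", "post.*PLT")),
  fxiii_post     = pick(bl, c("F\\.?XIII\\.?post", "post.*XIII"))
)

dir.create(dirname(out), recursive = TRUE, showWarnings = FALSE)
write.csv(cohort, out, row.names = FALSE, quote = FALSE)
cat("wrote", nrow(cohort), "subjects to", out, "\n")
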