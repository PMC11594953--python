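# Cut-offs banding each long-form scale into the four ordinal
# self-management categories.  Bounds are closed integer intervals
# [lo, hi]; for each scale the four intervals must partition
# [0, scale_max] with good > average > borderline > poor throughout.
#
# The published band edges overlap at two points (a 16-point score of
# exactly 6 and a 32-point score of exactly 20).  These tables resolve
# the overlap best-first: the better category keeps its printed lower
# bound.  Edit this file to re-resolve the ambiguity; the loader
# re-validates the partition.
schemes:
  16:
    good: [12, 16]
    average: [9, 11]
    borderline: [6, 8]
    poor: [0, 5]
  32:
    good: [20, 32]
    average: [17, 19]
    borderline: [12, 16]
    poor: [0, 11]
  48:
    good: [30, 48]
    average: [24, 29]
    borderline: [18, 23]
    poor: [0, 17]
  96:
    good: [56, 96]
    average: [49, 55]
    borderline: [41, 48]
    poor: [0, 40]
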