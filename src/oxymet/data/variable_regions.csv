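# Hypervariable regions of the bacterial 16S rRNA gene in E. coli
# coordinates (1-based, inclusive). This is the conventional table used for
# V-region indexing; boundaries differ by a few bases between sources, so
# the file is shipped as an editable resource rather than a constant.
region,start,end
V1,69,99
V2,137,242
V3,433,497
V4,576,682
V5,822,879
V6,986,1043
V7,1117,1173
V8,1243,1294
V9,1295,1435
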