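haplotype,80:sub,97:sub,161:sub,165:sub,195:indel,196:indel,254:indel,269:sub,289:sub,298:sub,448:sub,920:sub,944:sub,945:sub,946:sub,1004:sub,1035:sub,1062:sub,1124:sub,1150:indel,1285:indel,1372:sub,1375:sub
H1,A,C,T,G,-,-,-,G,A,G,G,G,C,A,A,T,A,G,G,*,-,T,G
H2,A,C,T,G,-,-,-,G,A,A,G,G,C,A,A,T,A,G,G,*,-,T,G
H3,A,C,T,G,-,-,-,G,A,G,G,G,A,A,A,T,A,G,G,*,-,T,G
H4,A,C,T,G,-,-,-,G,A,G,G,A,C,A,A,T,A,G,G,*,-,T,G
H5,A,C,T,G,-,-,-,G,A,G,G,G,C,C,A,T,A,G,G,*,-,T,G
H6,A,C,T,G,-,-,-,G,A,G,G,G,C,C,C,T,A,G,G,*,-,T,G
H7,G,T,T,T,A,-,-,T,G,G,G,G,C,A,A,C,A,G,T,-,†,C,C
H8,G,T,T,T,A,-,#,T,G,G,G,G,C,A,A,C,A,G,T,-,†,C,C
H9,G,T,T,T,A,-,-,A,G,G,G,G,C,A,A,C,A,G,T,-,†,C,C
H10,G,T,T,T,A,A,-,A,G,G,G,G,A,A,A,C,A,G,T,-,†,C,C
H11,G,T,T,T,A,-,-,T,G,G,G,G,C,C,A,C,A,G,T,-,†,C,C
H12,G,T,T,T,A,-,-,T,G,G,G,G,C,C,A,C,A,C,T,-,†,C,C
H13,G,T,C,T,A,-,-,T,G,G,G,G,C,C,A,C,A,C,T,-,†,C,C
H14,G,T,T,T,A,-,-,T,G,G,G,G,C,C,C,C,A,C,T,-,†,C,C
H15,G,T,T,T,A,-,-,T,G,G,G,G,C,C,C,C,C,C,T,-,†,C,C
H16,G,T,T,T,A,-,-,T,G,G,A,G,C,C,A,C,A,C,T,-,†,C,C
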