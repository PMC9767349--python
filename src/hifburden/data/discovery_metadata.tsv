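individual_id	status	disease
P01	case	MS
P02	case	OD
P03	case	OD
P04	case	OD
P05	case	MS
P06	case	OD
P07	case	MS
P08	case	OD
P09	case	OD
P10	case	OD
P11	case	OD
P12	case	MS
P13	case	OD
P14	case	OD
P15	case	OD
P16	case	OD
P17	case	OD
P18	case	OD
P19	case	MS
P20	case	MS
P21	case	MS
P22	case	OD
P23	case	OD
P24	case	OD
P25	case	OD
P26	case	OD
P27	case	OD
P28	case	OD
P29	case	OD
P30	case	OD
P31	case	OD
P32	case	OD
P33	case	OD
P34	case	OD
P35	case	OD
P36	case	OD
P37	case	OD
P38	case	OD
P39	case	OD
P40	case	OD
P41	case	OD
P42	case	OD
P43	case	OD
P44	case	OD
P45	case	OD
P46	case	OD
P47	case	OD
P48	case	OD
P49	case	OD
P50	case	OD
P51	case	OD
P52	case	OD
P53	case	OD
P54	case	OD
P55	case	OD
P56	case	OD
P57	case	OD
P58	case	OD
P59	case	OD
P60	case	OD
P61	case	OD
P62	case	OD
P63	case	OD
P64	case	OD
P65	case	OD
P66	case	OD
P67	case	OD
P68	case	OD
P69	case	OD
P70	case	OD
P71	case	OD
P72	case	OD
P73	case	OD
P74	case	OD
P75	case	OD
P76	case	OD
P77	case	OD
P78	case	OD
P79	case	MS
P80	case	MS
P81	case	MS
P82	case	MS
P83	case	MS
P84	case	MS
P85	case	MS
P86	case	MS
P87	case	MS
P88	case	MS
P89	case	MS
P90	case	MS
P91	case	MS
P92	case	MS
P93	case	MS
P94	case	MS
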